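"""Sequence data model, run-length time warping and posture discretization.

Behaviour is represented as a stream of discrete state labels (postures),
one per video frame.  Because an animal often holds the same posture over
several frames, consecutive duplicates are collapsed ("non-uniform time
warping"): the label sequence keeps only state *transitions* while the dwell
duration of each visit is recorded separately.  This makes the same
behaviour performed at different speeds map to the same label sequence.

Continuous posture descriptors (e.g. vectors of midline angles) are mapped
to labels by nearest-template assignment against a fixed template set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "RawLabelSequence",
    "WarpedSequence",
    "TemplateSet",
    "collapse_repeats",
    "discretize",
]

DEFAULT_ALPHABET_SIZE = 90


@dataclass(frozen=True)
class RawLabelSequence:
    """A frame-by-frame stream of positive integer state labels.

    Parameters
    ----------
    labels
        One label per frame, each >= 1.  Adjacent duplicates are expected
        (the animal dwells in a posture for several frames).
    frame_interval
        Time units per frame; used to express dwell durations in time
        units after warping.  ``None`` means durations stay in frames.
    """

    labels: tuple[int, ...]
    frame_interval: float | None = None

    def __init__(self, labels: Iterable[int], frame_interval: float | None = None):
        labels = tuple(int(x) for x in labels)
        if any(x < 1 for x in labels):
            raise ValueError("labels must be positive integers (>= 1)")
        if frame_interval is not None and frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "frame_interval", frame_interval)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class WarpedSequence:
    """A time-warped label sequence: transitions only, with dwell durations.

    Invariants: ``labels`` and ``durations`` have equal length, durations
    are positive, labels lie in ``[1, alphabet_size]`` and (in strict mode)
    no two adjacent labels are equal.  ``strict=False`` admits sequences
    with adjacent repeats — needed for controls such as i.i.d. uniform
    sampling that are deliberately not de-duplicated.
    """

    labels: tuple[int, ...]
    durations: tuple[float, ...]
    alphabet_size: int = DEFAULT_ALPHABET_SIZE
    strict: bool = field(default=True, compare=False, repr=False)

    def __init__(
        self,
        labels: Iterable[int],
        durations: Iterable[float] | None = None,
        alphabet_size: int = DEFAULT_ALPHABET_SIZE,
        strict: bool = True,
    ):
        labels = tuple(int(x) for x in labels)
        if durations is None:
            durations = (1.0,) * len(labels)
        else:
            durations = tuple(float(d) for d in durations)
        if len(labels) != len(durations):
            raise ValueError(
                f"labels ({len(labels)}) and durations ({len(durations)}) "
                "must have equal length"
            )
        if any(d <= 0 for d in durations):
            raise ValueError("all durations must be positive")
        if labels and (min(labels) < 1 or max(labels) > alphabet_size):
            raise ValueError(
                f"labels must lie in [1, alphabet_size={alphabet_size}]"
            )
        if strict and any(a == b for a, b in zip(labels, labels[1:])):
            raise ValueError("adjacent labels must differ in a warped sequence")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "alphabet_size", int(alphabet_size))
        object.__setattr__(self, "strict", bool(strict))

    def __len__(self) -> int:
        return len(self.labels)

    def expand(self, frame_interval: float = 1.0) -> RawLabelSequence:
        """Undo the time warping: repeat each label round(duration/frame_interval) times."""
        frames: list[int] = []
        for lab, dur in zip(self.labels, self.durations):
            n = int(round(dur / frame_interval))
            frames.extend([lab] * max(n, 1))
        return RawLabelSequence(frames, frame_interval=frame_interval)

    def mean_duration(self) -> float:
        if not self.durations:
            return float("nan")
        return float(np.mean(self.durations))


@dataclass(frozen=True)
class TemplateSet:
    """An ordered bank of posture templates (descriptor vectors).

    Template ``i`` (0-based internally) corresponds to label ``i + 1``.
    """

    templates: np.ndarray  # (k, dimension)

    def __init__(self, templates):
        arr = np.asarray(templates, dtype=float)
        if arr.ndim != 2:
            raise ValueError("templates must be a 2-D array (k, dimension)")
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 templates")
        object.__setattr__(self, "templates", arr)
        self.templates.setflags(write=False)

    @property
    def k(self) -> int:
        return int(self.templates.shape[0])

    @property
    def dimension(self) -> int:
        return int(self.templates.shape[1])


def collapse_repeats(seq: RawLabelSequence | Sequence[int]) -> WarpedSequence:
    """Collapse runs of identical labels, recording the dwell duration of each.

    ``{1,2,3,1,1,1,4,1}`` becomes labels ``{1,2,3,1,4,1}`` with durations
    ``{1,1,1,3,1,1}`` (times ``frame_interval`` when one is set).  The
    round trip through :meth:`WarpedSequence.expand` is exact.
    """
    if not isinstance(seq, RawLabelSequence):
        seq = RawLabelSequence(seq)
    labels = seq.labels
    interval = seq.frame_interval if seq.frame_interval is not None else 1.0
    out_labels: list[int] = []
    out_durs: list[float] = []
    for lab in labels:
        if out_labels and out_labels[-1] == lab:
            out_durs[-1] += interval
        else:
            out_labels.append(lab)
            out_durs.append(interval)
    alphabet = max(out_labels, default=1)
    alphabet = max(alphabet, DEFAULT_ALPHABET_SIZE)
    return WarpedSequence(out_labels, out_durs, alphabet_size=alphabet)


def discretize(descriptors, templates: TemplateSet) -> RawLabelSequence:
    """Assign each descriptor frame the 1-based label of its nearest template.

    Distance is Euclidean; ties go to the lowest template index, so the
    assignment is deterministic.
    """
    arr = np.asarray(descriptors, dtype=float)
    if arr.size == 0:
        return RawLabelSequence([])
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != templates.dimension:
        raise ValueError(
            f"descriptor dimension {arr.shape[1]} does not match "
            f"template dimension {templates.dimension}"
        )
    # Per-pair squared distances (not the Gram-expansion shortcut): exact
    # ties must resolve to the lowest template index, and argmin returns the
    # first minimum only when tied distances are bit-identical.
    d2 = cdist(arr, templates.templates, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1) + 1
    return RawLabelSequence(labels.tolist())
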