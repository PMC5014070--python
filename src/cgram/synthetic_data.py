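"""Synthetic cohorts with the statistical structure the analysis assumes.

A cohort emulates a multi-condition behavioural experiment: each individual
is a warped posture sequence drawn from a first-order base process (uniform
over the alphabet with no adjacent repeats, or a supplied Markov chain),
into which higher-order motifs are spliced at Poisson-spaced positions with
condition-specific rates.  Dwell durations are log-normal (median 3 frames)
to mimic the dwelling/roaming spread of real recordings.  Ground truth
(which motifs were planted, at which rates) ships with every cohort so
power and false-discovery tests are self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_sequences import WarpedSequence
from .null_models import MarkovModel, simulate_markov

__all__ = [
    "PlantedMotif",
    "CohortSpec",
    "Cohort",
    "generate_cohort",
    "generate_descriptor_stream",
]

DWELL_MEDIAN_FRAMES = 3.0
DWELL_SIGMA = 0.6  # log-scale s.d. of the log-normal dwell model


@dataclass(frozen=True)
class PlantedMotif:
    """A base-label motif and its per-condition insertion rate (per symbol)."""

    motif: tuple[int, ...]
    rates: Mapping[str, float]

    def __post_init__(self):
        motif = tuple(int(x) for x in self.motif)
        if len(motif) < 2:
            raise ValueError("planted motifs must have length >= 2")
        if any(a == b for a, b in zip(motif, motif[1:])):
            raise ValueError("planted motifs must have no adjacent equal labels")
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("insertion rates must be >= 0")
        object.__setattr__(self, "motif", motif)
        object.__setattr__(self, "rates", dict(self.rates))


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    ``n_per_condition`` individuals are generated for each condition label,
    each a sequence of ``sequence_length`` warped labels.  ``base_model``
    is either the string ``"uniform"`` (uniform next-label with no
    self-transitions) or a :class:`MarkovModel`.
    """

    conditions: tuple[str, ...]
    n_per_condition: int
    sequence_length: int
    alphabet_size: int = 90
    base_model: MarkovModel | str = "uniform"
    planted_motifs: tuple[PlantedMotif, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "conditions", tuple(str(c) for c in self.conditions)
        )
        object.__setattr__(
            self, "planted_motifs", tuple(self.planted_motifs)
        )
        if self.n_per_condition < 1:
            raise ValueError("n_per_condition must be >= 1")
        if self.sequence_length < 2:
            raise ValueError("sequence_length must be >= 2")
        if self.alphabet_size < 2:
            raise ValueError("alphabet_size must be >= 2")
        for pm in self.planted_motifs:
            if len(pm.motif) > self.sequence_length:
                raise ValueError("planted motif longer than sequence")
            if max(pm.motif) > self.alphabet_size:
                raise ValueError("planted motif label outside alphabet")


@dataclass(frozen=True)
class Cohort:
    """Generated individuals plus the ground truth they were built from."""

    sequences: tuple[WarpedSequence, ...]
    conditions: tuple[str, ...]  # per individual
    spec: CohortSpec

    @property
    def n_individuals(self) -> int:
        return len(self.sequences)

    def ground_truth(self) -> list[dict]:
        """Planted motifs with their per-condition insertion rates."""
        return [
            {"motif": pm.motif, "rates": dict(pm.rates)}
            for pm in self.spec.planted_motifs
        ]


def _uniform_no_repeat(alphabet: int, length: int, rng: np.random.Generator):
    """Uniform next label excluding the previous one (valid warped labels)."""
    labels = np.empty(length, dtype=int)
    labels[0] = rng.integers(1, alphabet + 1)
    draws = rng.integers(1, alphabet, size=length)  # in 1..alphabet-1
    for t in range(1, length):
        d = draws[t]
        labels[t] = d if d < labels[t - 1] else d + 1
    return labels.tolist()


def _splice(base: list[int], motif: tuple[int, ...], pos: int) -> list[int]:
    """Insert ``motif`` at ``pos``, repairing boundary repeats.

    If a base symbol touching the motif equals the adjacent motif label,
    that *base* symbol is dropped, keeping the planted motif intact.
    """
    left, right = base[:pos], base[pos:]
    if left and left[-1] == motif[0]:
        left = left[:-1]
    if right and right[0] == motif[-1]:
        right = right[1:]
    return left + list(motif) + right


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate every individual of a cohort, reproducibly under ``spec.seed``.

    Per individual: draw a base sequence, splice each planted motif in at
    ``Poisson(rate * length)`` uniformly placed positions for the
    individual's condition, truncate back to ``sequence_length`` labels and
    attach log-normal dwell durations.
    """
    rng = np.random.default_rng(spec.seed)
    sequences: list[WarpedSequence] = []
    conditions: list[str] = []
    for cond in spec.conditions:
        for _ in range(spec.n_per_condition):
            # overdraw so motif splices + truncation still leave full length
            margin = sum(len(pm.motif) + 2 for pm in spec.planted_motifs)
            base_len = spec.sequence_length + margin
            if isinstance(spec.base_model, MarkovModel):
                base = list(
                    simulate_markov(spec.base_model, base_len, seed=rng).labels
                )
            else:
                base = _uniform_no_repeat(spec.alphabet_size, base_len, rng)
            for pm in spec.planted_motifs:
                rate = pm.rates.get(cond, 0.0)
                n_ins = rng.poisson(rate * spec.sequence_length)
                for _ in range(n_ins):
                    pos = int(rng.integers(0, len(base) + 1))
                    base = _splice(base, pm.motif, pos)
            labels = base[: spec.sequence_length]
            durations = rng.lognormal(
                mean=np.log(DWELL_MEDIAN_FRAMES),
                sigma=DWELL_SIGMA,
                size=len(labels),
            )
            sequences.append(
                WarpedSequence(
                    labels,
                    durations.tolist(),
                    alphabet_size=spec.alphabet_size,
                )
            )
            conditions.append(cond)
    return Cohort(
        sequences=tuple(sequences),
        conditions=tuple(conditions),
        spec=spec,
    )


def generate_descriptor_stream(
    templates,
    label_seq: WarpedSequence,
    noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Continuous descriptor frames for a warped label sequence.

    Each label emits ``round(duration)`` frames of its template vector plus
    isotropic Gaussian noise — the forward model inverted by
    :func:`~cgram.core_sequences.discretize`.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    frames: list[np.ndarray] = []
    for lab, dur in zip(label_seq.labels, label_seq.durations):
        n = max(int(round(dur)), 1)
        base = templates.templates[lab - 1]
        for _ in range(n):
            if noise_sd > 0:
                frames.append(base + rng.normal(0.0, noise_sd, size=base.shape))
            else:
                frames.append(base.copy())
    if not frames:
        return np.empty((0, templates.dimension))
    return np.vstack(frames)
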