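"""Control sequence generators and compressibility-vs-length curves.

Real behavioural sequences sit between two extremes: an i.i.d. uniform
sequence over a large alphabet (essentially incompressible at the lengths
considered) and a deterministic cycle through the alphabet (compressibility
approaching 1).  Shuffled and sorted versions of an observed sequence give
bounds constrained to its label frequencies, and a first-order Markov chain
fitted to its transitions gives a more realistic null that still lacks
higher-order structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .compression import Config, compress
from .core_sequences import WarpedSequence

__all__ = [
    "MarkovModel",
    "uniform_random",
    "cyclic_deterministic",
    "shuffle",
    "sort_labels",
    "fit_markov",
    "simulate_markov",
    "compressibility_curve",
]

logger = logging.getLogger(__name__)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class MarkovModel:
    """First-order Markov chain over base labels with no self-transitions.

    The zero diagonal reflects the time-warped input: a warped sequence
    never repeats a label, so a chain fitted to one has no self-transitions
    and simulation must not reintroduce them.
    """

    states: tuple[int, ...]
    transition_matrix: np.ndarray  # row-stochastic, zero diagonal
    initial_distribution: np.ndarray

    def __init__(self, states, transition_matrix, initial_distribution):
        states = tuple(int(s) for s in states)
        tm = np.asarray(transition_matrix, dtype=float)
        init = np.asarray(initial_distribution, dtype=float)
        k = len(states)
        if tm.shape != (k, k):
            raise ValueError("transition matrix must be (k, k)")
        if init.shape != (k,):
            raise ValueError("initial distribution must have length k")
        if not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.abs(np.diag(tm)) > 1e-12):
            raise ValueError("self-transitions are not allowed (diagonal must be 0)")
        if not np.isclose(init.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "transition_matrix", tm)
        object.__setattr__(self, "initial_distribution", init)
        tm.setflags(write=False)
        init.setflags(write=False)


def uniform_random(alphabet: int, length: int, seed=None) -> WarpedSequence:
    """I.i.d. uniform labels over ``1..alphabet``.

    Sampling is plain i.i.d. — adjacent repeats are *not* removed (each
    occurs with probability 1/alphabet per step, negligible for the default
    90-label alphabet), so the result is constructed in non-strict mode.
    """
    if alphabet < 2:
        raise ValueError("alphabet must be >= 2")
    rng = _rng(seed)
    labels = rng.integers(1, alphabet + 1, size=length)
    return WarpedSequence(labels, alphabet_size=alphabet, strict=False)


def cyclic_deterministic(alphabet: int, length: int) -> WarpedSequence:
    """The symbols ``1..alphabet`` repeated in turn, truncated at ``length``."""
    if alphabet < 2:
        raise ValueError("alphabet must be >= 2")
    labels = [(i % alphabet) + 1 for i in range(length)]
    return WarpedSequence(labels, alphabet_size=alphabet)


def shuffle(seq: WarpedSequence, seed=None) -> WarpedSequence:
    """Random permutation of a sequence's (label, duration) pairs.

    Preserves the label multiset exactly while destroying temporal order;
    the permutation can create adjacent repeats, so the result is
    non-strict.
    """
    rng = _rng(seed)
    perm = rng.permutation(len(seq))
    labels = [seq.labels[i] for i in perm]
    durs = [seq.durations[i] for i in perm]
    return WarpedSequence(labels, durs, alphabet_size=seq.alphabet_size, strict=False)


def sort_labels(seq: WarpedSequence) -> list[int]:
    """Labels in ascending order — maximal runs, same label multiset.

    Returns a plain label list (it contains runs by construction, so it is
    not a valid warped sequence).
    """
    return sorted(seq.labels)


def fit_markov(seq: WarpedSequence, n_states: int | None = None) -> MarkovModel:
    """Empirical transition probabilities of a warped sequence.

    ``P[i][j] = count(i -> j) / count(i -> .)``.  States with no outgoing
    observations get a uniform row over the *other* states so simulation
    stays well defined at any length (logged when it happens).  The initial
    distribution is the empirical label distribution.
    """
    if len(seq) < 2:
        raise ValueError("need at least 2 labels to fit transitions")
    k = n_states if n_states is not None else seq.alphabet_size
    states = tuple(range(1, k + 1))
    counts = np.zeros((k, k), dtype=float)
    for a, b in zip(seq.labels, seq.labels[1:]):
        counts[a - 1, b - 1] += 1
    row_sums = counts.sum(axis=1)
    tm = np.zeros_like(counts)
    unseen = []
    for i in range(k):
        if row_sums[i] > 0:
            tm[i] = counts[i] / row_sums[i]
        else:
            unseen.append(i + 1)
            tm[i] = 1.0 / (k - 1)
            tm[i, i] = 0.0
    if unseen:
        logger.info(
            "fit_markov: %d state(s) with no outgoing transitions set to "
            "uniform over other states: %s",
            len(unseen),
            unseen[:10],
        )
    freq = np.bincount(np.asarray(seq.labels) - 1, minlength=k).astype(float)
    init = freq / freq.sum()
    return MarkovModel(states, tm, init)


def simulate_markov(model: MarkovModel, length: int, seed=None) -> WarpedSequence:
    """Sample a label sequence from a fitted chain (never emits self-transitions)."""
    rng = _rng(seed)
    k = len(model.states)
    if length == 0:
        return WarpedSequence([], alphabet_size=k)
    labels = np.empty(length, dtype=int)
    labels[0] = rng.choice(k, p=model.initial_distribution)
    # inverse-CDF sampling against precomputed row cumsums
    cum = np.cumsum(model.transition_matrix, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    for t in range(1, length):
        labels[t] = np.searchsorted(cum[labels[t - 1]], u[t], side="right")
    return WarpedSequence((labels + 1).tolist(), alphabet_size=k)


def compressibility_curve(
    generator: Callable[[int, np.random.Generator], WarpedSequence | Sequence[int]],
    lengths: Sequence[int],
    replicates: int = 1,
    cfg: Config = Config(),
    seed=None,
) -> pd.DataFrame:
    """Mean +/- s.d. compressibility as a function of sequence length.

    ``generator(length, rng)`` must return a sequence of at least that
    length (it is truncated to exactly ``length`` labels before
    compression).
    """
    rng = _rng(seed)
    rows = []
    for length in lengths:
        if length < 2:
            raise ValueError("lengths must be >= 2")
        vals = []
        for _ in range(replicates):
            seq = generator(length, rng)
            labels = seq.labels if isinstance(seq, WarpedSequence) else tuple(seq)
            alphabet = (
                seq.alphabet_size
                if isinstance(seq, WarpedSequence)
                else max(labels, default=0)
            )
            res = compress(labels[:length], cfg, alphabet_size=alphabet)
            vals.append(res.compressibility)
        rows.append(
            {
                "length": int(length),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if replicates > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
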