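"""Pooling of c-grams / n-grams across individuals and condition comparison.

Each individual's dictionary is expanded to base-label motifs and pooled
(keeping unique motifs only); every motif's frequency is then recomputed in
every individual — greedy non-overlapping occurrence count divided by the
warped-sequence length, so differences in overall activity between
individuals do not masquerade as motif differences.  Two n-gram baselines
use the same machinery: all n-grams up to a maximum length, and only the
top-k most frequent n-grams of each length per individual.

Motifs modulated between conditions ("hits") are detected with two-sided
Wilcoxon rank-sum tests on the per-individual frequencies, for every motif
and every unordered condition pair, corrected as one family with the
Benjamini-Yekutieli procedure (valid under arbitrary dependence, which the
heavily overlapping motifs guarantee) at a 5% false discovery rate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .compression import CompressionResult, _expansions, count_nonoverlapping
from .core_sequences import WarpedSequence

__all__ = [
    "MotifTable",
    "ComparisonResult",
    "pool_cgrams",
    "enumerate_ngrams",
    "top_frequent_ngrams",
    "compare_conditions",
    "by_adjust",
    "hit_summary",
    "frequency_rank_distribution",
]

ORIGIN_CGRAM = "cgram"
ORIGIN_ALL_NGRAM = "all_ngram"
ORIGIN_TOP_NGRAM = "top_frequent_ngram"


@dataclass(frozen=True)
class MotifTable:
    """Unique base-label motifs x individuals frequency matrix.

    ``frequencies[i, j]`` is motif ``i``'s non-overlapping occurrence count
    in individual ``j``'s warped sequence divided by that sequence's
    length.  ``origin`` records how each motif entered the pool.
    """

    motifs: tuple[tuple[int, ...], ...]
    origin: tuple[str, ...]
    frequencies: np.ndarray  # (n_motifs, n_individuals)
    conditions: tuple[str, ...]  # per individual

    def __post_init__(self):
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.shape != (len(self.motifs), len(self.conditions)):
            raise ValueError("frequencies must be (n_motifs, n_individuals)")
        if np.any(freq < 0):
            raise ValueError("frequencies must be non-negative")
        if len(set(self.motifs)) != len(self.motifs):
            raise ValueError("motifs must be unique")
        object.__setattr__(self, "frequencies", freq)

    @property
    def n_motifs(self) -> int:
        return len(self.motifs)

    @property
    def n_individuals(self) -> int:
        return len(self.conditions)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(
            ["-".join(map(str, m)) for m in self.motifs], name="motif"
        )
        df = pd.DataFrame(self.frequencies, index=idx)
        df.columns = [f"ind{j}" for j in range(self.n_individuals)]
        df.insert(0, "origin", self.origin)
        return df


@dataclass(frozen=True)
class ComparisonResult:
    """Per motif x condition-pair rank-sum statistics with BY-adjusted q-values.

    ``table`` columns: motif, pair, statistic, p, q, hit.  A motif is a hit
    when it is significant (q <= fdr_level) in at least one pair.
    """

    table: pd.DataFrame
    fdr_level: float

    def hits(self) -> list[tuple[int, ...]]:
        """Motifs significant in at least one condition pair."""
        flagged = self.table.loc[self.table["hit"], "motif"]
        seen: dict[tuple[int, ...], None] = {}
        for m in flagged:
            seen.setdefault(m)
        return list(seen)

    @property
    def n_hits(self) -> int:
        return len(self.hits())


def _labels_of(seq) -> tuple[int, ...]:
    return seq.labels if isinstance(seq, WarpedSequence) else tuple(seq)


def _frequency_matrix(
    motifs: Sequence[tuple[int, ...]],
    sequences: Sequence[WarpedSequence | Sequence[int]],
) -> np.ndarray:
    """Non-overlapping count / sequence length for every motif in every individual.

    Counts are grouped per motif length via a sliding-window index over each
    sequence, so the cost is O(total windows), not O(motifs x length).
    """
    lengths = sorted({len(m) for m in motifs})
    motif_set = set(motifs)
    freq = np.zeros((len(motifs), len(sequences)), dtype=float)
    index = {m: i for i, m in enumerate(motifs)}
    for j, seq in enumerate(sequences):
        labels = _labels_of(seq)
        n = len(labels)
        if n == 0:
            continue
        for w in lengths:
            occ: dict[tuple[int, ...], list[int]] = {}
            for i in range(n - w + 1):
                window = labels[i : i + w]
                if window in motif_set:
                    occ.setdefault(window, []).append(i)
            for motif, starts in occ.items():
                next_free = 0
                count = 0
                for s in starts:
                    if s >= next_free:
                        count += 1
                        next_free = s + w
                freq[index[motif], j] = count / n
    return freq


def pool_cgrams(
    results: Sequence[CompressionResult],
    sequences: Sequence[WarpedSequence | Sequence[int]],
    conditions: Sequence[str],
) -> MotifTable:
    """Pool every individual's dictionary into a unique-motif frequency table.

    Every rule of every individual is expanded to base labels,
    de-duplicated across the pool (in first-appearance order), and counted
    in *every* individual's sequence — a motif compressive for one worm may
    still occur, or be absent, in the others.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 individuals")
    if not (len(results) == len(sequences) == len(conditions)):
        raise ValueError("results, sequences and conditions must align")
    pooled: dict[tuple[int, ...], None] = {}
    for res in results:
        exp = _expansions(res.rules, res.alphabet_size)
        for rule in res.rules:
            pooled.setdefault(exp[rule.symbol])
    motifs = tuple(pooled)
    freq = _frequency_matrix(motifs, sequences)
    return MotifTable(
        motifs=motifs,
        origin=(ORIGIN_CGRAM,) * len(motifs),
        frequencies=freq,
        conditions=tuple(str(c) for c in conditions),
    )


def enumerate_ngrams(
    sequences: Sequence[WarpedSequence | Sequence[int]],
    conditions: Sequence[str],
    max_len: int = 10,
) -> MotifTable:
    """All distinct n-grams (1 <= n <= max_len) across the cohort."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(sequences) != len(conditions):
        raise ValueError("sequences and conditions must align")
    pooled: dict[tuple[int, ...], None] = {}
    for seq in sequences:
        labels = _labels_of(seq)
        n = len(labels)
        for w in range(1, min(max_len, n) + 1):
            for i in range(n - w + 1):
                pooled.setdefault(labels[i : i + w])
    motifs = tuple(pooled)
    freq = _frequency_matrix(motifs, sequences)
    return MotifTable(
        motifs=motifs,
        origin=(ORIGIN_ALL_NGRAM,) * len(motifs),
        frequencies=freq,
        conditions=tuple(str(c) for c in conditions),
    )


def top_frequent_ngrams(
    sequences: Sequence[WarpedSequence | Sequence[int]],
    conditions: Sequence[str],
    k: int = 5,
    max_len: int = 10,
) -> MotifTable:
    """The k most frequent n-grams of each length from each individual, pooled.

    Frequency ties are broken by the canonical motif order (ascending
    lexicographic), so the selection is deterministic.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    pooled: dict[tuple[int, ...], None] = {}
    for seq in sequences:
        labels = _labels_of(seq)
        n = len(labels)
        for w in range(1, min(max_len, n) + 1):
            occ: dict[tuple[int, ...], list[int]] = {}
            for i in range(n - w + 1):
                occ.setdefault(labels[i : i + w], []).append(i)
            counts = []
            for motif, starts in occ.items():
                next_free = 0
                c = 0
                for s in starts:
                    if s >= next_free:
                        c += 1
                        next_free = s + w
                counts.append((-c, motif))
            counts.sort()
            for _, motif in counts[:k]:
                pooled.setdefault(motif)
    motifs = tuple(pooled)
    freq = _frequency_matrix(motifs, sequences)
    return MotifTable(
        motifs=motifs,
        origin=(ORIGIN_TOP_NGRAM,) * len(motifs),
        frequencies=freq,
        conditions=tuple(str(c) for c in conditions),
    )


def by_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted q-values, in input order.

    ``q(i) = min_{j >= i} p(j) * m * c(m) / j`` on ascending-sorted
    p-values, with ``c(m) = sum_{h=1..m} 1/h``, capped at 1.  Valid under
    arbitrary dependence between the tests.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_by")
    return q


def compare_conditions(
    table: MotifTable, fdr: float = 0.05
) -> ComparisonResult:
    """Rank-sum tests for every motif and unordered condition pair, BY-corrected.

    One BY family spans all motifs and all pairs.  Frequencies constant
    across both groups carry no rank information and get p = 1.
    """
    conditions = sorted(set(table.conditions))
    if len(conditions) < 2:
        raise ValueError("need at least 2 conditions")
    cond_idx = {
        c: [j for j, cj in enumerate(table.conditions) if cj == c]
        for c in conditions
    }
    for c, idx in cond_idx.items():
        if len(idx) < 2:
            raise ValueError(f"condition {c!r} has fewer than 2 individuals")
    rows = []
    for a, b in itertools.combinations(conditions, 2):
        fa = table.frequencies[:, cond_idx[a]]
        fb = table.frequencies[:, cond_idx[b]]
        for i, motif in enumerate(table.motifs):
            x, y = fa[i], fb[i]
            if np.ptp(np.concatenate([x, y])) == 0.0:
                stat, p = float(len(x) * len(y) / 2.0), 1.0
            else:
                stat, p = mannwhitneyu(
                    x, y, alternative="two-sided", method="auto"
                )
            rows.append(
                {
                    "motif": motif,
                    "origin": table.origin[i],
                    "pair": (a, b),
                    "statistic": float(stat),
                    "p": float(p),
                }
            )
    df = pd.DataFrame(rows)
    df["q"] = by_adjust(df["p"].to_numpy())
    df["hit"] = df["q"] <= fdr
    return ComparisonResult(table=df, fdr_level=fdr)


def hit_summary(
    result: ComparisonResult, table: MotifTable
) -> pd.DataFrame:
    """Fraction of motifs that are hits, stratified by motif length and origin."""
    hit_set = set(result.hits())
    rows = []
    keys = sorted(
        {(len(m), o) for m, o in zip(table.motifs, table.origin)}
    )
    for length, origin in keys:
        group = [
            m
            for m, o in zip(table.motifs, table.origin)
            if len(m) == length and o == origin
        ]
        n_hits = sum(m in hit_set for m in group)
        rows.append(
            {
                "length": length,
                "origin": origin,
                "n_motifs": len(group),
                "n_hits": n_hits,
                "hit_fraction": n_hits / len(group),
            }
        )
    return pd.DataFrame(rows)


def frequency_rank_distribution(
    table: MotifTable, hits: Sequence[tuple[int, ...]]
) -> list[int]:
    """Best frequency rank each hit attains in any individual.

    Within each individual, motifs are ranked by frequency (rank 1 = most
    frequent; competition ranking on ties); each hit contributes its
    numerically smallest rank across individuals.
    """
    if not hits:
        return []
    freq = table.frequencies
    # competition rank: 1 + number of motifs strictly more frequent
    order = np.argsort(-freq, axis=0, kind="stable")
    ranks = np.empty_like(freq, dtype=int)
    for j in range(freq.shape[1]):
        col = freq[:, j]
        sorted_vals = col[order[:, j]]
        rank_of_sorted = np.empty(len(col), dtype=int)
        r = 1
        for pos in range(len(col)):
            if pos > 0 and sorted_vals[pos] < sorted_vals[pos - 1]:
                r = pos + 1
            rank_of_sorted[pos] = r
        ranks[order[:, j], j] = rank_of_sorted
    index = {m: i for i, m in enumerate(table.motifs)}
    out = []
    for m in hits:
        if m not in index:
            raise KeyError(f"hit motif {m} not in table")
        out.append(int(ranks[index[m]].min()))
    return out
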