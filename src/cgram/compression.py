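"""Offline compressive-heuristic dictionary compression of label sequences.

The algorithm iteratively finds the subsequence whose replacement by a new
dictionary symbol yields the largest net description-length saving

    S = W * N - (W + 1 + N)

where ``W`` is the subsequence length and ``N`` the number of (greedy,
non-overlapping) occurrences in the sequence as it stands at that
iteration.  ``W * N`` symbols disappear from the sequence; the dictionary
grows by ``W + 1`` (the body plus its new symbol) and ``N`` new symbols are
written back.  The most compressive subsequence is replaced, the rule is
recorded, and the procedure recurses on the partially compressed sequence
until no replacement saves at least one symbol.  Replaced subsequences may
themselves contain earlier dictionary symbols, so the dictionary encodes a
hierarchy of nested motifs ("c-grams").

Compression is lossless: expanding the dictionary recovers the input
exactly.  The *compressibility* of a sequence of uncompressed length ``l``
is the summed savings over all iterations divided by ``l`` — 0 for a
repeat-free sequence, approaching 1 for perfectly repetitive infinite
sequences — and serves as a scalar stereotypy phenotype.

The search is greedy (locally optimal per iteration, not globally optimal)
and, for speed, only subsequences up to length ``w_max`` (default 10) are
scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_sequences import WarpedSequence

__all__ = [
    "Config",
    "Rule",
    "CompressionResult",
    "Candidate",
    "DendrogramNode",
    "Arc",
    "savings",
    "count_nonoverlapping",
    "find_most_compressive",
    "compress",
    "decompress",
    "expand_cgram",
    "nesting_depth",
    "dendrogram",
    "arc_diagram",
    "chunked_phenotype",
]


@dataclass(frozen=True)
class Config:
    """Compression settings.

    w_max : longest subsequence length scored per iteration (>= 2).
    """

    w_max: int = 10

    def __post_init__(self):
        if self.w_max < 2:
            raise ValueError("w_max must be >= 2")


@dataclass(frozen=True)
class Rule:
    """One dictionary entry: ``symbol`` stands for ``body``.

    ``body`` may contain base labels and symbols of earlier rules only.
    ``starts`` are the 1-based start positions of the replaced occurrences
    in the sequence *as it existed at that iteration*; ``orig_starts`` are
    the same occurrences mapped back to the original uncompressed
    coordinates.
    """

    symbol: int
    body: tuple[int, ...]
    N: int
    savings: int
    starts: tuple[int, ...]
    orig_starts: tuple[int, ...]

    @property
    def W(self) -> int:
        return len(self.body)


@dataclass(frozen=True)
class Candidate:
    """The most compressive subsequence of one iteration, before replacement."""

    body: tuple[int, ...]
    N: int
    savings: int
    starts: tuple[int, ...]  # 1-based, current-iteration coordinates

    @property
    def W(self) -> int:
        return len(self.body)


@dataclass(frozen=True)
class CompressionResult:
    compressed: tuple[int, ...]
    rules: tuple[Rule, ...]
    l: int
    compressibility: float
    alphabet_size: int

    @property
    def total_savings(self) -> int:
        return sum(r.savings for r in self.rules)

    @property
    def dictionary_size(self) -> int:
        """Total symbols stored in the dictionary: sum over rules of W + 1."""
        return sum(r.W + 1 for r in self.rules)


def savings(W: int, N: int) -> int:
    """Net symbols saved by replacing a length-``W`` subsequence occurring ``N`` times."""
    if W < 1 or N < 1:
        raise ValueError("W and N must be >= 1")
    return W * N - (W + 1 + N)


def count_nonoverlapping(
    seq: Sequence[int], sub: Sequence[int]
) -> tuple[int, tuple[int, ...]]:
    """Greedy left-to-right count of non-overlapping occurrences of ``sub``.

    After a match at position ``p`` the scan resumes at ``p + len(sub)``.
    Returns ``(N, starts)`` with 1-based start positions.
    """
    sub = tuple(sub)
    if not sub:
        raise ValueError("sub must be non-empty")
    seq = tuple(seq)
    w = len(sub)
    starts: list[int] = []
    i = 0
    limit = len(seq) - w
    while i <= limit:
        if seq[i : i + w] == sub:
            starts.append(i + 1)
            i += w
        else:
            i += 1
    return len(starts), tuple(starts)


def _greedy_from_overlapping(starts: list[int], w: int) -> list[int]:
    """Reduce sorted overlapping 0-based starts to the greedy non-overlapping subset."""
    taken: list[int] = []
    next_free = 0
    for s in starts:
        if s >= next_free:
            taken.append(s)
            next_free = s + w
    return taken


def _candidate_scan(seq: Sequence[int], w_max: int):
    """Yield (body, N, greedy 0-based starts) for every unique subsequence
    with 2 <= W <= w_max occurring at least twice (greedily, non-overlapping)."""
    n = len(seq)
    seq = tuple(seq)
    for w in range(2, min(w_max, n) + 1):
        occ: dict[tuple[int, ...], list[int]] = {}
        for i in range(n - w + 1):
            occ.setdefault(seq[i : i + w], []).append(i)
        for body, starts in occ.items():
            if len(starts) < 2:
                continue
            greedy = _greedy_from_overlapping(starts, w)
            if len(greedy) >= 2:
                yield body, len(greedy), greedy


def find_most_compressive(
    seq: Sequence[int], cfg: Config = Config()
) -> Candidate | None:
    """The unique subsequence (2 <= W <= w_max, N >= 2) maximizing the savings.

    Returns ``None`` when no replacement saves at least one symbol.  Ties
    are broken by the canonical sort order of unique subsequences:
    ascending length, then lexicographic by labels — a total order, so the
    result is deterministic.
    """
    best_s = 0
    best_body: tuple[int, ...] | None = None
    best_n = 0
    best_starts: list[int] = []
    # _candidate_scan yields W ascending; within a W, dict order is first-
    # occurrence order, so the canonical comparison below is still needed.
    for body, n_occ, starts in _candidate_scan(seq, cfg.w_max):
        s = len(body) * n_occ - (len(body) + 1 + n_occ)
        if s > best_s or (
            s == best_s
            and best_body is not None
            and (len(body), body) < (len(best_body), best_body)
        ):
            best_s, best_body, best_n, best_starts = s, body, n_occ, starts
    if best_body is None or best_s < 1:
        return None
    return Candidate(
        body=best_body,
        N=best_n,
        savings=best_s,
        starts=tuple(p + 1 for p in best_starts),
    )


def compress(
    seq: WarpedSequence | Sequence[int],
    cfg: Config = Config(),
    alphabet_size: int | None = None,
) -> CompressionResult:
    """Iterated greedy replacement of the most compressive subsequence.

    New dictionary symbols are numbered ``alphabet_size + 1``,
    ``alphabet_size + 2``, ... in order of creation, so base labels and
    rule symbols stay disjoint.  When ``seq`` is a plain label sequence the
    alphabet size defaults to its largest label.
    """
    if isinstance(seq, WarpedSequence):
        labels = list(seq.labels)
        k = seq.alphabet_size
    else:
        labels = [int(x) for x in seq]
        k = max(labels, default=0)
    if alphabet_size is not None:
        k = alphabet_size
    l = len(labels)
    # orig_start[i]: 1-based position in the original sequence where the
    # expansion of token i begins; carried through replacements so arcs can
    # be drawn in original coordinates.
    orig_start = list(range(1, l + 1))

    rules: list[Rule] = []
    next_symbol = k + 1
    current = labels
    while True:
        cand = find_most_compressive(current, cfg)
        if cand is None:
            break
        w = cand.W
        starts0 = [p - 1 for p in cand.starts]
        rules.append(
            Rule(
                symbol=next_symbol,
                body=cand.body,
                N=cand.N,
                savings=cand.savings,
                starts=cand.starts,
                orig_starts=tuple(orig_start[p] for p in starts0),
            )
        )
        new_seq: list[int] = []
        new_orig: list[int] = []
        pos = 0
        for p in starts0:
            new_seq.extend(current[pos:p])
            new_orig.extend(orig_start[pos:p])
            new_seq.append(next_symbol)
            new_orig.append(orig_start[p])
            pos = p + w
        new_seq.extend(current[pos:])
        new_orig.extend(orig_start[pos:])
        current, orig_start = new_seq, new_orig
        next_symbol += 1

    total = sum(r.savings for r in rules)
    return CompressionResult(
        compressed=tuple(current),
        rules=tuple(rules),
        l=l,
        compressibility=(total / l) if l else 0.0,
        alphabet_size=k,
    )


def _expansions(
    rules: Iterable[Rule], alphabet_size: int
) -> dict[int, tuple[int, ...]]:
    """Expansion of every rule symbol down to base labels.

    Bodies reference only earlier symbols, so one pass in rule order
    suffices.
    """
    exp: dict[int, tuple[int, ...]] = {}
    for rule in rules:
        parts: list[int] = []
        for tok in rule.body:
            if tok in exp:
                parts.extend(exp[tok])
            elif 1 <= tok <= alphabet_size:
                parts.append(tok)
            else:
                raise KeyError(
                    f"rule {rule.symbol} references unknown symbol {tok}"
                )
        exp[rule.symbol] = tuple(parts)
    return exp


def decompress(result: CompressionResult) -> list[int]:
    """Recover the original sequence exactly from the compressed form + dictionary."""
    exp = _expansions(result.rules, result.alphabet_size)
    out: list[int] = []
    for tok in result.compressed:
        if tok in exp:
            out.extend(exp[tok])
        elif 1 <= tok <= result.alphabet_size:
            out.append(tok)
        else:
            raise KeyError(f"compressed stream contains unknown symbol {tok}")
    return out


def expand_cgram(
    rules: Sequence[Rule], symbol: int, alphabet_size: int | None = None
) -> tuple[int, ...]:
    """Fully expand a base label or rule symbol to its base-label sequence."""
    if alphabet_size is None:
        alphabet_size = (rules[0].symbol - 1) if rules else symbol
    if 1 <= symbol <= alphabet_size:
        return (symbol,)
    exp = _expansions(rules, alphabet_size)
    if symbol not in exp:
        raise KeyError(f"unknown symbol {symbol}")
    return exp[symbol]


def nesting_depth(
    rules: Sequence[Rule], symbol: int, alphabet_size: int | None = None
) -> int:
    """0 for base labels; 1 + the deepest body symbol otherwise."""
    if alphabet_size is None:
        alphabet_size = (rules[0].symbol - 1) if rules else symbol
    if 1 <= symbol <= alphabet_size:
        return 0
    by_symbol = {r.symbol: r for r in rules}
    if symbol not in by_symbol:
        raise KeyError(f"unknown symbol {symbol}")
    depth: dict[int, int] = {}
    for r in rules:  # rule order == dependency order
        depth[r.symbol] = 1 + max(
            (depth.get(tok, 0) for tok in r.body), default=0
        )
    return depth[symbol]


@dataclass(frozen=True)
class DendrogramNode:
    """A node of the nesting tree of a c-gram.

    Leaves are base labels (``count`` is None); internal nodes carry the
    occurrence count ``N`` recorded when their rule was created.
    """

    symbol: int
    count: int | None
    children: tuple["DendrogramNode", ...]

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.symbol]
        out: list[int] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def dendrogram(
    rules: Sequence[Rule], symbol: int, alphabet_size: int | None = None
) -> DendrogramNode:
    """The hierarchical structure of a c-gram as a tree down to base labels."""
    if alphabet_size is None:
        alphabet_size = (rules[0].symbol - 1) if rules else symbol
    by_symbol = {r.symbol: r for r in rules}

    def build(sym: int) -> DendrogramNode:
        if 1 <= sym <= alphabet_size:
            return DendrogramNode(symbol=sym, count=None, children=())
        if sym not in by_symbol:
            raise KeyError(f"unknown symbol {sym}")
        rule = by_symbol[sym]
        return DendrogramNode(
            symbol=sym,
            count=rule.N,
            children=tuple(build(tok) for tok in rule.body),
        )

    return build(symbol)


@dataclass(frozen=True)
class Arc:
    """One arc of an arc diagram: adjacent occurrences of the same motif.

    Positions are 1-based starts in the *original* sequence; ``width`` is
    the fully expanded motif length.
    """

    symbol: int
    start_a: int
    start_b: int
    width: int


def arc_diagram(result: CompressionResult) -> list[Arc]:
    """Arcs connecting consecutive occurrences of each dictionary motif."""
    exp = _expansions(result.rules, result.alphabet_size)
    arcs: list[Arc] = []
    for rule in result.rules:
        width = len(exp[rule.symbol])
        pos = rule.orig_starts
        for a, b in zip(pos, pos[1:]):
            arcs.append(Arc(symbol=rule.symbol, start_a=a, start_b=b, width=width))
    return arcs


def chunked_phenotype(
    seq: WarpedSequence,
    chunk_len: int = 500,
    cfg: Config = Config(),
) -> list[tuple[float, float]]:
    """Per-chunk (compressibility, mean state duration) phenotype pairs.

    The sequence is cut into consecutive non-overlapping chunks of exactly
    ``chunk_len`` labels (the trailing partial chunk is discarded, keeping
    compressibility comparable across individuals of different lengths);
    each chunk contributes its compressibility and the mean of its dwell
    durations.
    """
    if chunk_len < 2:
        raise ValueError("chunk_len must be >= 2")
    out: list[tuple[float, float]] = []
    n_chunks = len(seq) // chunk_len
    for c in range(n_chunks):
        lo, hi = c * chunk_len, (c + 1) * chunk_len
        labels = seq.labels[lo:hi]
        durs = seq.durations[lo:hi]
        res = compress(labels, cfg, alphabet_size=seq.alphabet_size)
        out.append((res.compressibility, float(np.mean(durs))))
    return out
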