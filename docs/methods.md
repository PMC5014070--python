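# Methods

## Model and procedure

`cgram` treats behaviour as a sequence of discrete state labels over an
alphabet of `k` postures (default `k = 90`). Continuous posture
descriptors, when given, are discretized by nearest-template assignment:
Euclidean distance on the raw descriptor vectors (consistent with the
k-means objective under which such template banks are usually learned),
with exact ties resolved to the lowest template index for determinism.
Template *learning* is deliberately out of scope; a small k-means
convenience is not provided because synthetic template banks are
constructed directly in tests.

Time warping is plain run-length collapsing: consecutive identical labels
merge into one, and the dwell duration of each visit (run length ×
frame interval) is stored alongside. Durations default to frames and are
only converted to time units when a frame interval is supplied. The
expansion by integer frame counts is an exact inverse, which the tests
assert as a round-trip property.

Compression is the offline compressive heuristic. Per iteration, every
unique subsequence of the *current* (partially compressed) sequence with
`2 ≤ W ≤ W_max` is scored by `S = W·N − (W+1+N)`; `W = 1` is excluded
because a 1-gram can never save symbols under this formula. `N` is the
greedy left-to-right non-overlapping occurrence count: after a match at
`p` the scan resumes at `p + W`. Greedy counting maximizes the
non-overlapping match count for a fixed pattern and makes the worked
two-symbol example come out to exactly 7 saved symbols of 19. The
maximal-`S` candidate (if `S ≥ 1`) is replaced everywhere by the next
fresh symbol (`k+1, k+2, …`), keeping base labels and rule symbols
disjoint and the creation order recoverable.

Tie rule: "first in the sorted list of unique subsequences" is
operationalized as ascending length, then lexicographic by integer label.
This is a total order, so compression is a deterministic function of the
input and `W_max`. Total savings are invariant to which tied candidate is
chosen; the canonical order is a determinism device, not a claim about any
particular historical implementation.

Every accepted rule saves at least one symbol, so the total description
length strictly decreases and the iteration terminates. Two identities are
enforced by tests on arbitrary inputs:

- accounting: `l = |compressed| + Σ(Wᵢ+1) + Σ Sᵢ`
- losslessness: expanding the dictionary under the compressed stream
  reproduces the input exactly.

Occurrence start positions are recorded twice per rule: in the coordinates
of the sequence at that iteration, and mapped back to original
coordinates (each token carries the original start of its expansion
through replacements). Arc diagrams connect consecutive occurrences of
each rule in original coordinates, with arc width equal to the fully
expanded motif length.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `W_max` | 10 | longest subsequence scored per iteration; 10 vs 15 changes results in < 10% of synthetic Markov sequences (tested) |
| alphabet size `k` | 90 | posture template count; new symbols are numbered from `k+1` |
| chunk length | 500 | labels per phenotype chunk; fixed length removes the length-dependence of compressibility |
| FDR level | 0.05 | Benjamini–Yekutieli control across all motifs × condition pairs |
| n-gram max length | 10 | baseline pools for comparison with c-grams |
| top-k n-grams | 5 | per length, per individual, in the frequent-n-gram baseline |

## Null models

Uniform random sequences are sampled plainly i.i.d. — adjacent repeats are
*not* removed (probability 1/k per step, negligible at k = 90), so these
sequences are admitted through the data model's non-strict path rather
than being silently de-duplicated. The deterministic cycle `1..k`
repeated gives the upper bound; its compressibility at length 990 with
`W_max = 10` is 872/990 ≈ 0.8808, frozen as a regression value after a
hand audit of the first iteration (any 10-gram of the cycle occurs 11
times non-overlapping: S = 110 − 22 = 88).

Markov chains are first-order with a structurally zero diagonal: fitted on
warped sequences the diagonal is zero automatically, and simulation must
not reintroduce self-transitions. Rows for states never observed to leave
are set uniform over the other states (logged) so simulation is well
defined at any length. Initial states are drawn from the empirical label
distribution; a stationary-distribution alternative would differ only in
the first step's statistics and was not pursued.

## Motif statistics

Motif frequency is defined as greedy non-overlapping occurrence count
divided by warped-sequence length. Length-normalization removes overall
activity differences between individuals, matching the per-individual
comparison design; counts-per-unit-time would additionally entangle dwell
durations with motif usage.

All motifs × all unordered condition pairs form **one** BY family — the
conservative reading when a single FDR level is quoted for a
multi-condition comparison. The BY adjustment is delegated to statsmodels
(`fdr_by`) and cross-checked in tests against a hand computation
(`p = {0.01, 0.02, 0.03} → q = 0.055` for all three, via `c(3) = 11/6`
and the step-up minimum). Rank-sum tests use scipy's Mann–Whitney U with
`method="auto"`: exact enumeration for small untied samples, normal
approximation with tie correction otherwise — appropriate because
frequency vectors contain many zero ties. Frequencies constant across both
groups carry no rank information and are assigned p = 1 (scipy's tie
correction degenerates there).

Motifs of length 1 appear in n-gram pools but never as c-grams (`W ≥ 2`
by construction).

## Synthetic cohorts

The generator emulates a multi-condition behavioural experiment: a base
process (uniform next-label excluding the previous label, or a supplied
Markov chain) with higher-order motifs spliced in at `Poisson(rate ×
length)` uniformly placed positions, rates per condition. When a splice
would create an adjacent repeat at a boundary, the *base* symbol at that
boundary is dropped, preserving the planted motif intact. Dwell durations
are log-normal with median 3 frames and log-s.d. 0.6 — a right-skewed
dwell distribution emulating the dwelling/roaming spread that the chunked
phenotype is designed to expose; real dwell distributions are not
calibrated. Ground truth (motifs and rates) ships with every cohort so
power and false-discovery tests are self-contained.

What the generator does **not** emulate: biomechanically realistic posture
dynamics, long-range non-stationarity (hunger, habituation), inter-individual
baseline variability beyond sampling noise, and recording artefacts.
Passing tests therefore demonstrate correctness of the machinery and the
direction of the published contrasts (c-grams are fewer and more often
condition-modulated than n-grams; uniform ≤ Markov ≤ motif-planted
compressibility), not the magnitudes seen in real recordings, which depend
on the actual worm data.

## Problem sizes and numerical choices

Stochastic suite sizes were chosen as the smallest giving stable, clearly
separated outcomes: 100 replicates for the uniform-random control
(printed mean ± s.d. is 1×10⁻⁴ ± 3×10⁻⁴), 200 sequences of length 500 for
`W_max` robustness, 200 two-condition null cohorts (6 individuals ×
300 labels, alphabet 30 — a small alphabet so that every cohort yields a
non-trivial c-gram pool) for the false-hit fraction, and the power check
at the stated design exactly (rate 0.02 vs 0, n = 20/condition, length
2000). The null false-hit fraction observed is ~0.1%, far under the 5%
level, as expected from BY's conservativeness.

Degenerate inputs: empty sequences compress to compressibility 0 with no
rules; sequences shorter than the chunk length yield an empty phenotype
list; `sort_labels` returns a plain list (documented — its runs violate
the warped-sequence invariant by construction).

## Known limitations

- The search is greedy per iteration; it does not find the globally
  optimal grammar, by design.
- Candidate scoring is `O(W_max · L)` per iteration with hashed windows;
  sequences of ~10⁴ labels compress in well under a second, but the
  all-n-gram pooling baseline grows quickly with cohort size and
  `max_len`.
- Frequency counting for pooled motifs is greedy non-overlapping; other
  conventions (overlapping counts, counts per unit time) would change
  absolute frequencies but not the machinery.
- `fit_markov` assumes the input is warped; fitting a sequence with
  adjacent repeats raises no error but the zero-diagonal constraint is
  then violated at validation.
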