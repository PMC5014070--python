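# cgram

Hierarchical dictionary compression for discrete behavioural sequences.

Automated tracking turns animal behaviour into long streams of discrete
states — for example, each video frame of a crawling *C. elegans* assigned
the nearest of 90 canonical midline postures. `cgram` asks how much
*structure* such a stream contains, using a minimum-description-length
idea: repeated subsequences that shorten the total description (sequence +
dictionary) are behavioural motifs, and the fraction of the sequence they
save is a scalar stereotypy phenotype. The package is for computational
ethologists and anyone comparing symbolic sequences across individuals or
conditions.

## The method

Input sequences are **time-warped**: runs of identical labels are collapsed
to a single label, with the dwell duration kept alongside, so behaviours
performed at different speeds share one label sequence.

Compression follows the offline *compressive heuristic*: at each iteration,
for every unique subsequence of length `2 ≤ W ≤ W_max` (default 10)
occurring `N ≥ 2` times (greedy, non-overlapping), compute the saving

```
S = W·N − (W + 1 + N)
```

(`W·N` symbols leave the sequence; the dictionary grows by `W + 1` and `N`
new symbols are written back). The subsequence with maximal `S` is replaced
by a fresh symbol and recorded as a rule; ties go to the first subsequence
in the sorted list of unique subsequences (ascending length, then
lexicographic). The procedure recurses until no replacement saves a symbol,
so the dictionary entries — **c-grams** — can nest. Compression is lossless,
and

```
compressibility = Σ S / l        (l = uncompressed length)
```

is 0 for a repeat-free sequence and approaches 1 for perfectly repetitive
infinite ones.

Around the core algorithm the package provides: null models (uniform
random, deterministic cycle, shuffled, sorted, fitted first-order Markov
chains), a chunked compressibility-vs-mean-dwell phenotype, pooled-motif
frequency tables, and cross-condition motif detection via Wilcoxon
rank-sum tests with Benjamini–Yekutieli FDR control, plus a synthetic
cohort generator with planted motifs for power and false-discovery checks.

## Worked example

The classic two-symbol illustration:

```python
from cgram import compress, decompress

seq = [1,2,1,1,2,1,2,2,1,2,1,1,2,1,2,2,1,2,1]   # 19 symbols
res = compress(seq)
print("compressed:", res.compressed)
for r in res.rules:
    print(f"rule {r.symbol} -> {r.body}  W={r.W} N={r.N} S={r.savings}")
print("l =", res.l, " total savings =", res.total_savings,
      " dictionary =", res.dictionary_size,
      " compressibility =", round(res.compressibility, 4))
print("lossless:", decompress(res) == seq)
```

prints

```
compressed: (3, 4, 4)
rule 3 -> (1, 2, 1)  W=3 N=5 S=6
rule 4 -> (3, 2, 2, 3)  W=4 N=2 S=1
l = 19  total savings = 7  dictionary = 9  compressibility = 0.3684
lossless: True
```

The first iteration replaces `{1,2,1}` (5 occurrences, saving 6 symbols);
the second replaces one of two equally compressive 4-grams (saving 1 more).
Seven of 19 symbols are saved in total — the compressed sequence has 3
symbols and the dictionary 9 — giving compressibility 7/19 ≈ 37%. The
second rule contains the first: nesting like this is how larger behavioural
units re-use smaller ones.

## Command line

```sh
cgram compress --wmax 10 --dict out.json --arcs out.tsv input.seq
cgram simulate --model uniform --alphabet 90 --length 1000 --reps 100 --seed 7 --out sims/
cgram compare --motifs cgram --fdr 0.05 --conditions cond.tsv --out hits.tsv seqs/*.seq
cgram phenotype --chunk 500 --out pheno.tsv seqs/*.seq
cgram fixtures --spec cohort.yaml --out cohort/
```

Sequence files are plain text: one label per line with an optional second
duration column, or a single delimited line.

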