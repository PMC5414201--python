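# kdisjoint

Exhaustive, alignment-free mining of **k-disjoint** DNA sequences: given a
query set *A* and a reference ("taboo") set *B* of FASTA files, find every
length-*W* subsequence of *A* whose Hamming distance to **every** length-*W*
subsequence of *B* — forward and reverse-complement strand — is greater than
*k*. The complement set (windows within *k* mismatches of some taboo window)
is the *k*-intersection.

This matters wherever "unique" must mean more than "not an exact repeat":
padlock-probe targets for strain-level infection diagnostics tolerate single
mismatches, so probes should sit in sequence that is several mismatches away
from everything else; CRISPR guide selection benefits from the same
pre-filter to reduce off-target edits; and mapping a mutated or
phage-carrying genome against its unmutated reference turns every planted
substitution, inversion breakpoint or insertion into a cluster of k-disjoint
windows. Because the method is exhaustive (evidence of absence, not just
presence), it reports *all* qualifying windows — something seed-and-extend
aligners with dynamic repeat masking cannot guarantee.

## Method

Three ideas make the exhaustive scan practical:

1. **N-coding.** Every word of fixed length *N* ∈ {3, 4, 5} over the ordered
   five-letter alphabet A < C < G < N < T (N is the canonical unknown base)
   maps to its lexicographic rank, an integer in [0, 5^N). A window of
   length *W* (a multiple of *N*; the largest valid *N* is chosen) becomes a
   vector of *W/N* integer codes.
2. **Mismatch matrix.** A precomputed 5^N × 5^N byte table *M* holds the
   Hamming distance between every pair of decoded words, so the distance
   between two windows is the sum of *W/N* table look-ups, each comparison
   early-terminating once the running count exceeds *k*.
3. **Two-level partitioned index.** Taboo vectors are stored in sub-lists
   addressed by their first two codes (x₁, x₂). For a query vector only the
   addresses (i, j) with M(x₁, i) + M(x₂, j) ≤ k can hold a within-*k*
   match, so for k = 0 a single sub-list is probed and for small k the
   search touches a vanishing fraction of the index — while remaining exact.

A self-exclusion mode supports uniqueness mining *within* one genome (the
same file as query and taboo): each window's own exact occurrence is
discounted, so a window is reported iff it occurs exactly once and nothing
else lies within *k*.

The package also ships a synthetic benchmark layer — seeded random genomes,
planted transition substitutions (A↔G, C↔T), segment inversions and foreign
insertions, plus an exhaustive all-pairs brute-force reference — used by the
test-suite to verify the indexed engine exactly.

## Worked example

Plant three transition substitutions in a 10 kb random genome and find the
windows that no longer occur in the original:

```python
from pathlib import Path
from kdisjoint import (generate_genome, inject_substitutions,
                       sample_positions, write_fasta)
from kdisjoint.cli import parse_args, run_pipeline

genome = generate_genome(10_000, seed=7, record_id="chr1")
sites = sample_positions(10_000, 3, seed=8, margin=30, min_separation=90)
mutated, plans = inject_substitutions(genome, sites)  # sites 2361, 3281, 7183

Path("query").mkdir(); Path("taboo").mkdir()
write_fasta([mutated], "query/sample.fa")
write_fasta([genome], "taboo/reference.fa")

summary = run_pipeline(parse_args(
    ["--query-dir", "query", "--taboo-dir", "taboo",
     "--out", "out", "-W", "30", "-k", "0"]))
```

or equivalently from the shell: `kdisjoint --query-dir query --taboo-dir
taboo --out out -W 30 -k 0`. The run logs

```
W=30 -> N=5 (vectors of length 6)
index: 19942 vectors in 19757 sub-lists (max sub-list 2)
90/9971 windows disjoint (0.90%; 1.77% of query territory)
```

19,942 = 2 × (10000 − 30 + 1) taboo windows (both strands) were indexed, and
exactly 90 = 3 × 30 of the 9,971 query windows are 0-disjoint: each planted
substitution makes the 30 windows overlapping it unique. `out/sample.disjoint.tsv`
lists them as `record_id  position  sequence` (1-based positions):

```
# kdisjoint v1.0.0  W=30  k=0  N=5  mode=d  self_exclude=False
# record_id  position  sequence
chr1  2332  TTCCTAGGGTACTCACTTTCCAACTGCCAT
chr1  2333  TCCTAGGGTACTCACTTTCCAACTGCCATC
...
```

The summary also reports the *territory* fraction — the share of query
letters covered by the union of disjoint windows (1.77% here) — alongside
the window-count fraction. `--mode a` writes the intersection file too,
`--self-exclude` switches to within-genome uniqueness mining, and `--bed`
exports disjoint spans as 0-based half-open BED for downstream probe or
guide design.

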