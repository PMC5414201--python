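# Methods

## Problem

Given sets *A* (query) and *B* (taboo) of DNA sequences, a window length
*W* and a mismatch threshold *k*, the *k-disjoint* set of *A* against *B*
is every length-*W* substring of *A* whose Hamming distance (substitutions
only, no indels) to every length-*W* substring of *B* — both strands —
exceeds *k*. Its complement is the *k-intersection*. For *k* = 0 the
problem reduces to exact-uniqueness mining; larger *k* gives the stricter
notion of uniqueness needed for padlock-probe and CRISPR-guide target
pre-filtering and for detecting substitutions, inversions and insertions
against a reference.

## Encoding (`ncode`)

Words of length *N* ∈ {3, 4, 5} over the ordered alphabet A < C < G < N < T
are mapped to their lexicographic rank (base-σ positional value, σ = 5).
For a window length *W* the largest *N* dividing *W* is chosen; *W* must be
≥ 6 so that the encoded vector has at least the two leading codes the index
needs. *N* is capped at 5 because the precomputed mismatch matrix — the
dense σ^N × σ^N byte table of Hamming distances between decoded words —
grows as σ^(2N) (5^10 ≈ 9.8 M entries at N = 5, ~10 MB). Distances between
windows are sums of *W/N* matrix look-ups with early termination; the
capped distance routine returns `cap + 1` on overshoot rather than the true
distance, since callers only ever test `<= k`.

The unknown base N is an ordinary fifth letter: N–N contributes 0
mismatches, N–anything-else contributes 1. That is what a Hamming matrix
over the five-letter alphabet computes; whether unknown bases should
instead mismatch everything is a modelling choice we deliberately did not
expose as a toggle — sanitization maps every non-ACGT input character
(IUPAC ambiguity codes, gaps, stray symbols) to N, so the alternative would
make dirty regions globally "unique", which is rarely wanted in a
uniqueness pre-filter.

## Fragmentation (`fragmenter`)

FASTA files (optionally gzipped) are read with Biopython; records are
uppercased (ASCII-only case folding — Unicode uppercasing can change string
length) and sanitized as above. Coordinates are 1-based, inclusive, forward
strand. Query windows are taken from the forward strand only; the taboo
side is fragmented on both strands, so a query window matching the reverse
strand of a taboo sequence is still an intersection. Records shorter than
*W* produce a logged warning and no windows, so mixed-length directories
run to completion. Window encoding is vectorized: the code of the *N*-gram
at every offset is computed once per sequence (a sliding-window dot product
with the digit powers), and each window gathers its *W/N* codes by stride.

## Index (`dictree`)

Taboo vectors are partitioned into sub-lists keyed by their first two codes
(a two-level nested dictionary; empty sub-lists are never materialized, as
5^10 potential addresses would dominate memory for small inputs). Exactly
two index levels are used — deeper partitioning buys little once sub-lists
hold only a handful of vectors, which is already the case for genome-scale
inputs (expected sub-list size ≈ L_B/σ^(2N) under uniform composition).

The index also counts the exact multiplicity of every stored vector. This
serves two purposes: an O(1) exact-match shortcut during classification,
and the self-comparison protocol, where a genome is both query and taboo
and each window's single exact self-occurrence must be discounted.

For a query vector *x* and budget *k*, a within-*k* match can only live at
an address (i, j) with M(x₁, i) + M(x₂, j) ≤ k — the first two codes alone
already account for that much distance. Candidate addresses are enumerated
from precomputed distance shells around x₁ (all codes at exact distance d,
cached per code) rather than scanning all σ^N codes per query.

## Classification (`filter_engine`)

A window is labelled `intersection` as soon as any stored vector within *k*
is found, `disjoint` when the candidate-address search is exhausted. The
search first consults the multiplicity table (distance-0 hit), then walks
candidate first-level codes in ascending shell distance d₁; within each
occupied first-level entry it iterates the *stored* second-level codes and
filters them by the remaining budget, because the handful of occupied
second codes is almost always smaller than the distance-ball around x₂.
This means sub-lists are not visited in globally ascending d₁+d₂ order;
any visit order is correct (the result is existence, not a minimum), and
the exact-match shortcut already captures the main early-exit win.
Remaining vector elements are compared with early termination at the
residual budget.

Self-exclusion semantics: a window is disjoint iff its exact vector occurs
at most once in the index *and* no distinct vector lies within *k*. A
palindromic window (its own reverse complement) is indexed twice by the
two-strand fragmentation, acquires multiplicity 2, and is therefore never
disjoint under self-exclusion — documented behaviour, matching the
intuition that such a site also occurs on the opposite strand.

*k* values above 5 are permitted with a warning: the search stays exact but
the candidate-address count (and empirically the runtime) grows roughly an
order of magnitude per additional mismatch.

Multi-threading contract: windows are split into at most `threads`
contiguous ranges whose sizes differ by at most one; each range is
classified independently against the read-only index and results are
concatenated in range order, so output is byte-identical for any thread
count. (In CPython the benefit is modest for the pure-Python search loop;
the contract is determinism, not a speed-up guarantee.)

## Synthetic benchmarks and the reference scan (`synthetic`)

Random genomes are i.i.d. uniform over ACGT, fully seeded. Planted
alterations mirror the simulated detection experiments:

- **Substitutions** apply the transition map A↔G, C↔T at sampled sites
  (an N at a planned site is a logged no-op — synthetic genomes are N-free,
  but user-supplied ones need not be).
- **Inversions** replace a segment by its reverse complement (an
  involution; palindromic segments are fixed points).
- **Insertions** splice a donor segment — optionally carrying its own
  transition mutations — before a given position; plan coordinates are in
  the mutated record so recovery can be assessed directly on scan output.

`brute_force_kdisjoint` is the ground truth: every query window is compared
against every taboo window on both strands with no encoding, no index and
no pruning. The positionwise letter-agreement counts for all pairs are
evaluated as one-hot inner products (five indicator channels per position,
a single BLAS matrix product per query chunk), which keeps the exhaustive
all-pairs scan fast enough to run at the tens-of-kilobases scale; a
pure-Python letter-loop reference in the test-suite cross-checks the
vectorized computation on tiny inputs, so the engine-vs-oracle comparison
never collapses onto a single code path. The per-window minimum distance is
computed once and thresholded for each *k*, since it does not depend on *k*.

A site counts as *recovered* when at least one disjoint-labelled window
overlaps its altered territory (the substituted base, the inverted segment,
or the spliced donor span).

## Problem sizes in the test-suite

The simulated experiments run at desk scale — genomes of 50–100 kb rather
than the megabase genomes the protocols come from — with the protocol
itself (site counts, mutation types, *W*, *k*) kept intact: 100 kb / 5
transitions / W=30 / k=0 for point mutations; 50 kb host with four 70 bp
insertions carrying 0–3 mutations / W=70 / k=3; 50 kb with an 80 bp
inversion / W=30 / k=0; 50 kb self-comparison / W=20 / k=0. The master
correctness property — exact equality between the indexed engine and the
brute-force reference — is swept over W ∈ {12, 15, 20, 30}, k ∈ {0..3} and
five seeds on 2 kb query / 10 kb taboo instances. Genome-scale runs
(mammalian chromosomes against whole genomes, k = 5 probe mining) are
supported by the same code paths but need external genome downloads and
hours of compute, so they are not part of the automated suite.

What the synthetic generator does *not* emulate: realistic base
composition, GC skew, repeat families, or sequencing error. Passing tests
therefore demonstrate algorithmic exactness (the engine equals the
exhaustive definition), not biological performance on repeat-rich genomes —
on real data the *fractions* of disjoint windows will differ, but the
labels remain exact by construction.

## Numerical and edge-case choices

- `choose_n` rejects window lengths divisible by none of 3, 4, 5 (or
  shorter than 6), naming the nearest valid lengths on both sides.
- Empty taboo input yields a valid empty index; every query window is then
  disjoint. The CLI, by contrast, requires at least one FASTA file per
  directory and exits non-zero otherwise.
- Ties and ordering: output is strictly (file name order, record order,
  1-based position); re-running an identical configuration produces
  byte-identical files (no timestamps in outputs).
- Output dialect: three TSV columns (record_id, position, sequence) — the
  record id disambiguates multi-record FASTA files; mode `a` writes
  `.disjoint.tsv` and `.intersection.tsv` per query file. The run summary
  reports both the window-count disjoint fraction and the genomic-territory
  fraction (union of disjoint spans over query length). Optional BED export
  converts spans to 0-based half-open coordinates.
- Identical words at different query positions are all reported; no
  deduplication across positions.

## Known limitations

- Substitution distance only; indels shift every downstream window and are
  visible only as runs of disjoint windows, not as alignments.
- Query-side reverse complements are not searched (the taboo side carries
  both strands); a query whose reverse complement — but not the window
  itself — is within *k* of taboo sequence is still reported disjoint.
- The whole taboo index lives in memory (O(L_B · W/N) integers); genomes
  beyond a few hundred megabases need more RAM than a laptop.
- The self-exclusion multiplicity rule treats palindromic windows as
  non-unique (see above); applications that want strand-blind uniqueness of
  palindromes would need a different discounting rule.
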