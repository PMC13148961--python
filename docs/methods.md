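# Methods

## Model and assumptions

`pepbloom` treats peptide-to-reference assignment as an approximate
set-membership problem. A reference bin is reduced to its set of distinct
amino-acid k-mers; a query peptide is assigned to a bin when a sufficient
fraction of its own k-mers are members of the bin's set. The data structure
is the interleaved Bloom filter (IBF): *b* equal-size Bloom filters over a
shared set of *H* hash functions, stored position-major so each of the *n*
bit positions holds a contiguous *b*-bit sub-vector and one probe answers
all bins at once.

The assumptions this rests on:

- **Membership, not alignment.** No positional or gap information is used;
  a peptide that shares k-mers with a bin through convergence or
  conservation is indistinguishable from a true product of that bin. The
  per-bin score ranks evidence; it is not an FDR-controlled identification.
- **Set semantics.** Repeated k-mers inside one peptide or one bin count
  once. The count matrix entry C[u,v] is therefore bounded by y_u, the
  number of distinct k-mers of peptide u, and the assignment threshold D
  compares C[u,v] against the real-valued x = y_u·D/100 without rounding.
- **One-sided errors.** Bloom filters produce no false negatives; every
  inserted k-mer is always found. False positives occur at a configurable
  rate p per (k-mer, bin) probe and are what the sizing rule controls.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| k | 5 | residues | short enough that 5–30-residue tryptic peptides yield several k-mers, long enough (20^5 = 3.2M) that random collisions are rare |
| target FPR p | 0.01 | probability | per-k-mer, per-bin false-positive budget; drives filter sizing |
| hash count H | 3 | — | standard Bloom operating point near the optimum for this p |
| split size M | 64 | bins/IBF | aligns each IBF's sub-vectors with machine words; batches size independently |
| assignment D | 100 | % of y | full-coverage criterion; 80 and 70 are the documented relaxed presets |
| min confidence | 0.70 | [0,1] | high-confidence regime of de novo score distributions; 0.50 is the relaxed preset for mutation-rich searches |
| mutation score | 25 | summed half-bit units | cumulative BLOSUM62 score a variant k-mer must reach; at k=5 self-scores span 20 (AAAAA) to 55 (WWWWW), so 25 admits conservative exchanges for most k-mers |
| minimizer window | 0 (off) | k-mers | optional sketching; proteins are short, so the default keeps every k-mer |

K-mers are packed into 64-bit integers at 5 bits per residue (alphabetical
ordinals, first residue most significant), capping k at 12. This keeps
codes order-preserving per position and makes numeric minimizer ordering
deterministic with no hash shuffling.

## Sizing

Each IBF is sized from its own batch: `maxKmers` is the exact distinct
k-mer count of the batch's heaviest bin (computed after mutation expansion
and minimizer reduction, since that is the set the filter must hold), and

    n = ceil(-1 / (r^(1/(H·maxKmers)) - 1)),   r = 1 - p^(1/H).

This inversion is exact: tests verify that n keeps the predicted rate
within p while n−1 exceeds it. Empty bins are floored at maxKmers = 1 and
retained as empty columns so bin indices stay aligned with the input.
Interleaving means every bin in a batch pays for the largest bin's size;
the split/batch mechanism exists precisely to limit that waste.

## Hashing

The H hash functions are one 64-bit avalanche mix (the splitmix64
finalizer) applied to `code XOR seed_h`, with H distinct seeds derived
deterministically from a base seed and recorded in the index header.
Rebuilding with the same inputs and configuration produces a byte-identical
archive. The mix passes the implicit uniformity check of the acceptance
measurement: empirical false-positive rates of sized filters sit at their
predicted values.

## Mutation mode

Variant generation scores a candidate k-mer v against the original by the
cumulative substitution score `sum_i S(kmer_i, v_i)` (BLOSUM62 by default,
any symmetric NCBI-layout matrix accepted) and keeps v when the sum meets
the threshold. A per-position threshold was rejected: single BLOSUM62
entries top out at 11, so meaningful thresholds like 25 are only coherent
as sums. Enumeration is depth-first over per-residue candidate lists
pre-sorted by descending score (ties alphabetical, for reproducible
indexes) with branch-and-bound pruning: a branch is cut when its partial
score plus the best possible completion cannot reach the threshold, and
the sorted order lets one failure cut all remaining siblings at that
depth. The pruned search is tested equal to exhaustive 20^k enumeration.
The original k-mer is always retained even when its self-score misses the
threshold, so unmutated references remain queryable. Expansion happens at
index-build time; queries are never expanded.

## Minimizers with mutation

Minimizer selection needs positional order, which a mutation-expanded
*set* of variants no longer has. When both modes are enabled, pepbloom
therefore selects minimizers over each sequence's ordered original k-mers
first and then expands the selected k-mers; with either mode alone the
question does not arise. Minimizers are applied identically at build and
query time — a requirement for membership semantics, though substring
queries against minimizer-sketched references remain inherently lossy
(a peptide's windows differ from its parent protein's), which is why the
mode defaults to off for short peptides.

## Synthetic data

The fixture generator emulates the structure of a known-composition
mixture experiment: uniform-composition random proteins grouped into
labelled bins, tryptic digestion (cleave after K/R except before P, keep
5–30 residues), queries sampled from known source bins, at most one
BLOSUM62-guided substitution per peptide (replacement scoring ≥ 0 against
the original — the conservative exchanges both de novo errors and true
variants favour), random-composition decoys, and Beta(8,2) confidence
scores. Defaults: 10 bins × 5 proteins of 120–400 residues, 200 query
peptides, no noise, no decoys — noise is opted into per experiment.

What it does **not** emulate: realistic amino-acid composition (uniform by
default, configurable), homology between bins, missed cleavages, spectra
or retention time, and length- or context-dependent de novo error
profiles. Passing planted-recovery tests therefore demonstrates the
correctness of the indexing/counting/scoring machinery and its
false-positive calibration — not classification accuracy on real
metaproteomes, where shared peptides between related taxa dominate the
error budget.

## Numerical and degenerate-input choices

- x = y·D/100 is compared in real arithmetic; no floor/ceiling.
- Peptides shorter than k are dropped at filtering with a logged count;
  duplicate peptide sequences collapse to the maximum confidence.
- k-mer windows containing non-canonical residues (X, B, Z, U, O, J, *)
  are skipped individually; the rest of the sequence still contributes.
- Bin order is input order throughout (never sorted); score ties in the
  per-bin report break by bin order.
- Empty query sets and all-blacklisted databases are errors; empty bins
  and empty sequences are warnings.
- Serialized indexes are numpy archives with JSON headers and packed bit
  matrices; loading reproduces the bit matrix exactly, and all
  configuration needed to query coherently (k, modes, seeds) travels in
  the header.

## Problem sizes

The test suite and the acceptance measurement run on deliberately small
instances chosen to exercise every code path with tight oracles: filters
of 10^4 elements probed 10^5 times for rate calibration, oracle
equivalence on filters up to 256 bits × 8 bins, brute-force variant
checks at k ≤ 3, and planted-recovery fixtures of 10 bins × 2 proteins
with 60–150 query peptides. These sizes make exhaustive and simulation
oracles exact or tightly bounded; the data structure itself scales by
construction (per-batch sizing is independent of database size).

## Known limitations

- Scores rank bins; they are not calibrated probabilities and carry no
  FDR control.
- No LCA-style rollup across taxonomic ranks; bins are flat.
- Mutation mode models substitutions only — no insertions, deletions, or
  PTM mass shifts.
- Counting queries load each IBF's full bit matrix in memory.
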