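# pepbloom

Fast taxonomic and protein-level classification of *de novo* sequenced
peptides against large protein reference databases, using partitioned
**interleaved Bloom filters** (IBFs) over amino-acid k-mers — alignment-free,
with optional BLOSUM62-based error tolerance.

## Who this is for

De novo peptide sequencing (Casanovo, SMSNet, …) produces peptide sequences
directly from MS/MS spectra, with a per-peptide confidence score but no
database context. `pepbloom` answers the follow-up question: *which
reference proteins, proteomes or taxa are these peptides most consistent
with?* It is a screening tool for metaproteomics and proteogenomics — it
trades alignment statistics for approximate k-mer membership queries that
index and search databases of thousands of reference bins in seconds.

## The method

**Index.** Each reference bin *B_i* (a protein, proteome or taxon group)
contributes its distinct k-mers (default k = 5), each packed into a 64-bit
integer (5 bits per residue). The bins of one batch share an IBF: *b*
equal-size Bloom filters interleaved so each of the *n* bit positions holds
a *b*-bit sub-vector, letting one probe answer membership for all bins at
once. A bin holding *m* elements with *H* hash functions has false-positive
rate

    p = (1 − (1 − 1/n)^(H·m))^H

and each filter is sized to its own content via the closed-form inversion

    n = ⌈ −1 / (r^(1/(H·maxKmers)) − 1) ⌉ ,   r = 1 − p^(1/H)

where `maxKmers` is the largest distinct-k-mer count over the batch's bins.
Defaults: p = 0.01, H = 3. Large databases are partitioned into batches of
`--split-size` bins (divide and conquer), each batch independently sized;
a blacklist file removes over-represented references up front. Optional
modes: forward-strand minimizer sketching, I/L collapse, and **mutation
mode**, which expands every reference k-mer into all variants whose
cumulative BLOSUM62 score `Σ_i S(kmer_i, v_i)` meets a threshold
(branch-and-bound over candidates pre-sorted by descending score), so
peptides carrying conservative substitutions still match.

**Query.** Peptides are confidence-filtered (default ≥ 0.70), k-merized
identically, and counted against every bin, giving the count matrix
`C[u,v]` = number of peptide *u*'s distinct k-mers present in bin *v*. With
`y_u` k-mers in peptide *u* and assignment threshold *D* (percent),

    L[u,v] = 1  iff  C[u,v] ≥ y_u · D/100 ,      S_B = Σ_u L[u,B] / z

— the lookup matrix and the per-bin assignment score (fraction of the *z*
query peptides assigned to bin *B*). D = 100 demands full k-mer coverage.

## Worked example

```bash
# 1. a synthetic 4-proteome database + 40 query peptides from bin002
cat > spec.yaml <<EOF
n_bins: 4
proteins_per_bin: 2
n_query_peptides: 40
source_bins: [bin002]
seed: 5
EOF
pepbloom simulate --spec spec.yaml --out sim/
# wrote 4-bin reference and 40 query peptides -> sim/

# 2. index it (two IBFs of two bins each)
pepbloom build --fasta sim/reference.fasta --grouping sim/grouping.tsv \
               --out index.npz --split-size 2
# indexed 4 bins in 2 IBF(s) -> index.npz

# 3. classify the peptides at full k-mer coverage (D = 100)
pepbloom query --index index.npz --peptides sim/peptides.tsv \
               --out results/ --min-confidence 0
# queried 23/40 peptides against 4 bins -> results/
```

`results/bins.tsv` then ranks the bins:

```
bin_label  peptides_passing  score_S  unique_peptides
bin002     23                1.0      23
bin000     0                 0.0      0
bin001     0                 0.0      0
bin003     0                 0.0      0
```

All 23 retained peptides (40 drawn, duplicates collapsed) are assigned to
the planted source proteome `bin002` with score S = 1.0 — every k-mer of
every peptide is found in that bin — and no peptide is assigned elsewhere.
`results/peptides.tsv` lists each peptide's confidence, its k-mer count
`y`, the bins it was assigned to with their counts, and whether the
assignment was unique. With `--mutate --mutation-score 25` at build time
the same search also tolerates single conservative substitutions.

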