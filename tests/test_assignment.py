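"""Count matrix, lookup thresholding, bin scores, and planted recovery."""

import math

import numpy as np
import pytest

from pepbloom.assignment import (
    AssignmentResult,
    PeptideRecord,
    assign,
    bin_scores,
    bin_summary,
    count_matrix,
    filter_peptides,
    lookup_matrix,
    peptide_query_codes,
    peptide_report,
)
from pepbloom.ibf import false_positive_rate
from pepbloom.index import BuildConfig, build_index, load_bins
from pepbloom.kmer import KmerConfig
from pepbloom.mutation import MutationConfig
from pepbloom.simulate import FixtureSpec, generate_queries, generate_reference


def fixture_index(tmp_path, spec, config=None):
    ref = generate_reference(spec)
    fasta = tmp_path / "ref.fasta"
    grouping = tmp_path / "grouping.tsv"
    fasta.write_text(ref.fasta_text)
    grouping.write_text(ref.grouping_text)
    bins = load_bins(fasta, grouping)
    return ref, build_index(bins, config or BuildConfig(split_size=4))


class TestFilterPeptides:
    def test_confidence_boundary_is_inclusive(self):
        records = [
            PeptideRecord("PEPTIDEK", 0.9),
            PeptideRecord("ELVISLIVES", 0.70),
            PeptideRecord("AAAAAGGGGG", 0.69),
        ]
        kept = filter_peptides(records, 0.70, k=5)
        assert [r.sequence for r in kept] == ["PEPTIDEK", "ELVISLIVES"]

    def test_zero_threshold_keeps_length_valid(self):
        records = [PeptideRecord("PEPTI", 0.1), PeptideRecord("AAA", 0.9)]
        kept = filter_peptides(records, 0.0, k=5)
        assert [r.sequence for r in kept] == ["PEPTI"]

    def test_duplicates_keep_max_confidence(self):
        records = [
            PeptideRecord("PEPTIDEK", 0.8),
            PeptideRecord("PEPTIDEK", 0.95),
        ]
        kept = filter_peptides(records, 0.5, k=5)
        assert len(kept) == 1
        assert kept[0].confidence == 0.95

    def test_record_validation(self):
        with pytest.raises(ValueError):
            PeptideRecord("", 0.5)
        with pytest.raises(ValueError):
            PeptideRecord("PEPTIDE", 1.5)


def manual_result(counts, y, labels=None):
    counts = np.asarray(counts)
    labels = labels or [f"b{i}" for i in range(counts.shape[1])]
    peptides = [
        PeptideRecord(f"PEPTIDE{'K' * u}", 1.0) for u in range(counts.shape[0])
    ]
    return AssignmentResult(
        peptides=peptides,
        bin_labels=labels,
        counts=counts,
        y=np.asarray(y),
    )


class TestLookupAndScores:
    def test_threshold_arithmetic_no_rounding(self):
        # y=5 at D=80 gives x=4.0: a count of 4 passes, 3 does not
        result = manual_result([[4, 3]], [5])
        lookup_matrix(result, 80.0)
        assert result.lookup.tolist() == [[True, False]]

    def test_full_coverage_requires_all_kmers(self):
        result = manual_result([[5, 4, 0]], [5])
        lookup_matrix(result, 100.0)
        assert result.lookup.tolist() == [[True, False, False]]

    def test_lowering_d_never_clears_a_bit(self):
        counts = np.array([[4, 3, 1], [5, 2, 0]])
        strict = lookup_matrix(manual_result(counts, [5, 5]), 80.0).lookup
        relaxed = lookup_matrix(manual_result(counts, [5, 5]), 70.0).lookup
        assert (relaxed | strict).tolist() == relaxed.tolist()

    def test_invalid_threshold_rejected(self):
        for bad in (0.0, -5.0, 101.0):
            with pytest.raises(ValueError):
                lookup_matrix(manual_result([[1]], [1]), bad)

    def test_score_is_column_mean(self):
        result = manual_result([[1], [1], [0], [0]], [1, 1, 1, 1])
        lookup_matrix(result, 100.0)
        bin_scores(result)
        assert result.scores[0] == pytest.approx(0.5)

    def test_all_assigned_scores_one(self):
        result = manual_result([[1], [1]], [1, 1])
        bin_scores(lookup_matrix(result, 100.0))
        assert result.scores[0] == pytest.approx(1.0)

    def test_score_mass_conserves_set_bits(self):
        rng = np.random.default_rng(8)
        counts = rng.integers(0, 6, size=(20, 7))
        y = np.full(20, 5)
        result = bin_scores(lookup_matrix(manual_result(counts, y), 60.0))
        z = len(result.peptides)
        assert result.scores.sum() * z == pytest.approx(result.lookup.sum())


class TestCountMatrix:
    def test_planted_peptide_counts_equal_y(self, tmp_path):
        spec = FixtureSpec(seed=11, n_bins=4, proteins_per_bin=2)
        ref, index = fixture_index(tmp_path, spec)
        label, seq = next(iter(ref.proteins.values()))
        pep = seq[10:25]
        result = count_matrix(index, [PeptideRecord(pep, 1.0)])
        v = result.bin_labels.index(label)
        assert result.y[0] == len(
            peptide_query_codes(pep, index.config.kmer)
        )
        assert result.counts[0, v] == result.y[0]

    def test_matches_per_ibf_oracle(self, tmp_path):
        # the global row must be exactly the concatenation of independent
        # per-IBF counting queries in directory order
        spec = FixtureSpec(seed=21, n_bins=7, proteins_per_bin=2,
                           n_query_peptides=30)
        ref, index = fixture_index(
            tmp_path, spec, BuildConfig(split_size=3)
        )
        queries = generate_queries(spec, ref)
        peptides = [
            PeptideRecord(p, 1.0)
            for p in queries.truth["peptide"].unique()
        ]
        result = count_matrix(index, peptides)
        for u, rec in enumerate(peptides):
            codes = peptide_query_codes(rec.sequence, index.config.kmer)
            expected = np.concatenate(
                [ibf.query_counts(codes) for ibf in index.ibfs]
            )
            assert np.array_equal(result.counts[u], expected)

    def test_mismatched_config_rejected(self, tmp_path):
        spec = FixtureSpec(seed=3, n_bins=2, proteins_per_bin=1)
        _, index = fixture_index(tmp_path, spec)
        with pytest.raises(ValueError, match="does not match"):
            count_matrix(
                index, [PeptideRecord("PEPTIDEK", 1.0)], KmerConfig(k=4)
            )


class TestEndToEnd:
    def test_planted_recovery_noiseless(self, tmp_path):
        """Peptides sampled from one bin: that bin scores S=1 at D=100 and
        off-target bins stay within the Bloom false-positive expectation."""
        spec = FixtureSpec(
            seed=42, n_bins=10, n_query_peptides=150, source_bins=("bin004",)
        )
        ref, index = fixture_index(tmp_path, spec)
        queries = generate_queries(spec, ref)
        peptides = filter_peptides(
            [
                PeptideRecord(p, 1.0)
                for p in queries.truth["peptide"]
            ],
            0.0,
            k=index.config.kmer.k,
        )
        result = assign(index, peptides, threshold_d=100.0)
        target = result.bin_labels.index("bin004")
        assert result.scores[target] == pytest.approx(1.0)
        # off-target: peptide passes iff all y k-mers are false positives;
        # dominated by the shortest peptides, bound via the per-kmer rate
        z = len(peptides)
        ibf0 = index.ibfs[0]
        per_kmer = false_positive_rate(
            ibf0.params.bits_per_bin, ibf0.params.max_kmers,
            ibf0.params.hash_count,
        )
        y_min = min(result.y)
        p_pep = per_kmer ** y_min
        bound = z * p_pep + 3 * math.sqrt(z * p_pep * (1 - p_pep))
        for v, label in enumerate(result.bin_labels):
            if v != target:
                assert result.lookup[:, v].sum() <= max(bound, 3)

    def test_mutation_expansion_improves_noisy_recall(self, tmp_path):
        """One conservative substitution per peptide: the BLOSUM62-expanded
        index must recover strictly more planted peptides at D=100."""
        spec = FixtureSpec(
            seed=77, n_bins=6, proteins_per_bin=3, n_query_peptides=60,
            substitution_rate=1.0, source_bins=("bin001",),
        )
        ref = generate_reference(spec)
        fasta = tmp_path / "ref.fasta"
        grouping = tmp_path / "g.tsv"
        fasta.write_text(ref.fasta_text)
        grouping.write_text(ref.grouping_text)
        bins = load_bins(fasta, grouping)
        queries = generate_queries(spec, ref)
        peptides = filter_peptides(
            [PeptideRecord(p, 1.0) for p in queries.truth["peptide"]],
            0.0, k=5,
        )
        plain = build_index(bins, BuildConfig(split_size=3))
        expanded = build_index(
            bins,
            BuildConfig(
                split_size=3,
                mutation=MutationConfig(enabled=True, score_threshold=20),
            ),
        )
        recalls = []
        for index in (plain, expanded):
            result = assign(index, peptides, threshold_d=100.0)
            v = result.bin_labels.index("bin001")
            recalls.append(result.lookup[:, v].mean())
        assert recalls[1] > recalls[0]

    def test_score_invariant_to_peptide_order_and_batching(self, tmp_path):
        spec = FixtureSpec(seed=13, n_bins=8, n_query_peptides=40)
        ref, index1 = fixture_index(tmp_path, spec, BuildConfig(split_size=8))
        fasta = tmp_path / "ref.fasta"
        grouping = tmp_path / "grouping.tsv"
        bins = load_bins(fasta, grouping)
        index2 = build_index(bins, BuildConfig(split_size=3))
        queries = generate_queries(spec, ref)
        peptides = filter_peptides(
            [PeptideRecord(p, 1.0) for p in queries.truth["peptide"]],
            0.0, k=5,
        )
        res_a = assign(index1, peptides, 100.0)
        res_b = assign(index1, list(reversed(peptides)), 100.0)
        res_c = assign(index2, peptides, 100.0)
        assert np.allclose(res_a.scores, res_b.scores)
        assert np.allclose(res_a.scores, res_c.scores)


class TestReports:
    def test_summary_and_peptide_tables(self):
        result = manual_result([[3, 0], [3, 3], [0, 0]], [3, 3, 3])
        result = bin_scores(lookup_matrix(result, 100.0))
        summary = bin_summary(result)
        assert summary.iloc[0]["bin_label"] == "b0"
        assert summary.iloc[0]["peptides_passing"] == 2
        assert summary.iloc[0]["score_S"] == pytest.approx(2 / 3)
        assert summary.iloc[0]["unique_peptides"] == 1  # row 1 hits both bins
        report = peptide_report(result)
        assert report["unique"].tolist() == [True, False, False]
        assert report["assigned_bins"].iloc[1] == "b0:3;b1:3"
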