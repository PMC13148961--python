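"""Query-side peptide classification: count matrix, lookup matrix, scores.

Each query peptide u is decomposed into its distinct k-mers (y_u of them)
and counted against every user bin, giving the count matrix entry c_uv.
The assignment threshold D (a percentage) converts counts into the binary
lookup matrix:

    x_u = y_u * D / 100            (real-valued, no rounding)
    l_uv = 1  iff  c_uv >= x_u

D = 100 is the full-coverage criterion: every k-mer of the peptide must be
supported by the bin. The per-bin assignment score is the column mean

    S_B = (sum_u l_uB) / z

with z the number of peptides queried — the fraction of the sample
assigned to bin B. Multi-assignment is allowed; peptides whose lookup row
sums to exactly 1 are flagged as uniquely assigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .index import MultiIndex
from .kmer import KmerConfig, encode, kmerize, minimizers

logger = logging.getLogger(__name__)

DEFAULT_MIN_CONFIDENCE = 0.70
RELAXED_MIN_CONFIDENCE = 0.50  # for mutation-rich searches
DEFAULT_THRESHOLD_D = 100.0


@dataclass(frozen=True)
class PeptideRecord:
    """A de novo peptide with its peptide-level confidence (the mean of
    the residue-level confidences, in [0, 1])."""

    sequence: str
    confidence: float = 1.0
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(
                f"confidence must be in [0, 1], got {self.confidence}"
            )


@dataclass
class AssignmentResult:
    """Count matrix C (peptides x bins), y vector, lookup matrix L, and
    per-bin scores S for one query set."""

    peptides: list[PeptideRecord]
    bin_labels: list[str]
    counts: np.ndarray  # (u, v) int
    y: np.ndarray  # (u,) distinct query k-mers per peptide
    lookup: np.ndarray | None = None  # (u, v) bool
    scores: np.ndarray | None = None  # (v,) float
    threshold_d: float | None = None


def read_peptides(path: str | Path) -> list[PeptideRecord]:
    """Read a peptide list (TSV or CSV): sequence, confidence[, source].

    A header row is detected by the second field not parsing as a number.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split(sep)
    header: int | None = 0
    if len(fields) >= 2:
        try:
            float(fields[1])
            header = None
        except ValueError:
            header = 0
    df = pd.read_csv(path, sep=sep, header=header)
    df.columns = ["sequence", "confidence", "source_tag"][: len(df.columns)]
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PeptideRecord(
                sequence=str(row.sequence).upper(),
                confidence=float(row.confidence),
                source_tag=str(getattr(row, "source_tag", "") or ""),
            )
        )
    return records


def filter_peptides(
    records: list[PeptideRecord],
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    k: int = 5,
) -> list[PeptideRecord]:
    """Confidence filter + dedup.

    Keeps records with confidence >= min_confidence and length >= k
    (shorter peptides produce no k-mers); duplicate sequences collapse to
    one record carrying the maximum confidence. Input order of first
    occurrence is preserved.
    """
    best: dict[str, PeptideRecord] = {}
    order: list[str] = []
    n_short = 0
    n_lowconf = 0
    for rec in records:
        if rec.confidence < min_confidence:
            n_lowconf += 1
            continue
        if len(rec.sequence) < k:
            n_short += 1
            continue
        if rec.sequence not in best:
            best[rec.sequence] = rec
            order.append(rec.sequence)
        elif rec.confidence > best[rec.sequence].confidence:
            best[rec.sequence] = rec
    if n_short or n_lowconf:
        logger.info(
            "filter_peptides dropped %d low-confidence and %d sub-k-length "
            "records (kept %d)", n_lowconf, n_short, len(order),
        )
    return [best[s] for s in order]


def peptide_query_codes(sequence: str, config: KmerConfig) -> set[int]:
    """The distinct encoded k-mers actually queried for one peptide,
    minimizer-reduced when the index was built with minimizers."""
    kmers, _ = kmerize(sequence, config)
    codes = [encode(km, config) for _, km in kmers]
    if config.minimizer_window and codes:
        return minimizers(codes, config.minimizer_window)
    return set(codes)


def count_matrix(
    index: MultiIndex,
    peptides: list[PeptideRecord],
    config: KmerConfig | None = None,
) -> AssignmentResult:
    """Build the count matrix C and the per-peptide k-mer totals y.

    ``config`` must match the index's k-merization settings; by default it
    is taken from the index itself. Each peptide's distinct k-mer codes are
    queried against every IBF and the global row is stitched together via
    the bin directory.
    """
    index_config = index.config.kmer
    if config is None:
        config = index_config
    elif config != index_config:
        raise ValueError(
            f"query k-mer config {config} does not match index config "
            f"{index_config}"
        )
    labels = index.bin_labels
    counts = np.zeros((len(peptides), len(labels)), dtype=np.int64)
    y = np.zeros(len(peptides), dtype=np.int64)
    for u, rec in enumerate(peptides):
        codes = peptide_query_codes(rec.sequence, config)
        y[u] = len(codes)
        if codes:
            counts[u, :] = index.query_counts(codes)
    return AssignmentResult(
        peptides=peptides, bin_labels=labels, counts=counts, y=y
    )


def lookup_matrix(
    result: AssignmentResult, threshold_d: float = DEFAULT_THRESHOLD_D
) -> AssignmentResult:
    """Threshold C into the binary lookup matrix L.

    x_u = y_u * D / 100 is compared as a real number (no rounding), so at
    D = 100 a peptide is assigned only where every one of its k-mers hit.
    """
    if not (0.0 < threshold_d <= 100.0):
        raise ValueError(f"threshold D must be in (0, 100], got {threshold_d}")
    x = result.y * (threshold_d / 100.0)
    result.lookup = result.counts >= x[:, None]
    # peptides with y = 0 have nothing to support an assignment
    result.lookup[result.y == 0, :] = False
    result.threshold_d = threshold_d
    return result


def bin_scores(result: AssignmentResult) -> AssignmentResult:
    """Per-bin assignment score S: the column mean of the lookup matrix."""
    if result.lookup is None:
        raise ValueError("lookup matrix not built; call lookup_matrix first")
    z = len(result.peptides)
    if z == 0:
        raise ValueError("no peptides after filtering")
    result.scores = result.lookup.sum(axis=0) / z
    return result


def assign(
    index: MultiIndex,
    peptides: list[PeptideRecord],
    threshold_d: float = DEFAULT_THRESHOLD_D,
) -> AssignmentResult:
    """count_matrix -> lookup_matrix -> bin_scores in one call."""
    return bin_scores(lookup_matrix(count_matrix(index, peptides), threshold_d))


def bin_summary(result: AssignmentResult) -> pd.DataFrame:
    """Per-bin report: assigned peptides, score S, uniquely assigned count.

    Sorted by S descending, ties broken by bin order, so the top row is
    the best-supported reference. Both the raw assigned-peptide count and
    the score fraction are emitted so either ranking can be used.
    """
    if result.scores is None:
        raise ValueError("scores not computed; call bin_scores first")
    L = result.lookup
    unique_rows = L.sum(axis=1) == 1
    df = pd.DataFrame(
        {
            "bin_label": result.bin_labels,
            "peptides_passing": L.sum(axis=0),
            "score_S": result.scores,
            "unique_peptides": L[unique_rows, :].sum(axis=0),
        }
    )
    df["input_order"] = np.arange(len(df))
    df = df.sort_values(
        ["score_S", "input_order"], ascending=[False, True], kind="stable"
    ).drop(columns="input_order")
    return df.reset_index(drop=True)


def peptide_report(result: AssignmentResult) -> pd.DataFrame:
    """Per-peptide report: confidence, y, assigned bins with their counts,
    and whether the assignment is unique (exactly one bin)."""
    if result.lookup is None:
        raise ValueError("lookup matrix not built; call lookup_matrix first")
    rows = []
    labels = np.array(result.bin_labels)
    for u, rec in enumerate(result.peptides):
        hit = np.flatnonzero(result.lookup[u])
        rows.append(
            {
                "peptide": rec.sequence,
                "confidence": rec.confidence,
                "y_kmers": int(result.y[u]),
                "n_assigned_bins": len(hit),
                "unique": len(hit) == 1,
                "assigned_bins": ";".join(
                    f"{labels[v]}:{result.counts[u, v]}" for v in hit
                ),
            }
        )
    return pd.DataFrame(rows)


def write_reports(result: AssignmentResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bin_summary(result).to_csv(out / "bins.tsv", sep="\t", index=False)
    peptide_report(result).to_csv(out / "peptides.tsv", sep="\t", index=False)
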