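"""Seeded synthetic reference databases and de novo-style peptide queries.

Emulates the structure of a lab-assembled mixture evaluation: a reference
database of known bins (proteomes), tryptic peptides sampled from known
source bins, optional single BLOSUM62-guided substitutions emulating
sequencing errors or genuine variants, decoy peptides from no bin, and
sampled per-peptide confidence scores. Every output is deterministic for a
fixed seed, and the ground-truth tables suffice to score planted-bin
recovery end to end.

What this generator does NOT emulate: realistic residue composition unless
configured (the default is uniform), missed cleavages, spectra, retention
times, and the length-dependent error profiles of real de novo models.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kmer import CANONICAL_ALPHABET
from .mutation import SubstitutionModel, load_blosum62

MIN_TRYPTIC_LENGTH = 5
MAX_TRYPTIC_LENGTH = 30


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults give a 10-bin database with a few hundred tryptic peptides
    per bin and noiseless, decoy-free queries; noise is opted into via
    ``substitution_rate`` and ``decoy_fraction``.
    """

    n_bins: int = 10
    proteins_per_bin: int = 5
    protein_length: tuple[int, int] = (120, 400)
    residue_distribution: dict[str, float] | None = None  # None = uniform
    n_query_peptides: int = 200
    peptide_length: tuple[int, int] = (MIN_TRYPTIC_LENGTH, MAX_TRYPTIC_LENGTH)
    substitution_rate: float = 0.0
    decoy_fraction: float = 0.0
    confidence_beta: tuple[float, float] = (8.0, 2.0)
    source_bins: tuple[str, ...] | None = None  # None = all bins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.proteins_per_bin < 1:
            raise ValueError("n_bins and proteins_per_bin must be >= 1")
        for p in (self.substitution_rate, self.decoy_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0, 1]: {p}")

    def residue_probs(self) -> np.ndarray:
        if self.residue_distribution is None:
            return np.full(len(CANONICAL_ALPHABET), 1 / len(CANONICAL_ALPHABET))
        probs = np.array(
            [self.residue_distribution.get(aa, 0.0) for aa in CANONICAL_ALPHABET]
        )
        total = probs.sum()
        if total <= 0:
            raise ValueError("residue distribution sums to zero")
        return probs / total


@dataclass
class ReferenceFixture:
    fasta_text: str
    grouping_text: str
    #: protein ID -> (bin label, sequence)
    proteins: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def bin_labels(self) -> list[str]:
        seen: list[str] = []
        for label, _ in self.proteins.values():
            if label not in seen:
                seen.append(label)
        return seen


@dataclass
class QueryFixture:
    peptides_text: str  # TSV: peptide, confidence
    truth_text: str  # TSV: peptide, origin bin label or "decoy"
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _random_protein(rng: np.random.Generator, length: int, probs: np.ndarray) -> str:
    letters = rng.choice(list(CANONICAL_ALPHABET), size=length, p=probs)
    return "".join(letters)


def generate_reference(spec: FixtureSpec) -> ReferenceFixture:
    """Random proteins grouped into labelled bins (FASTA + grouping TSV)."""
    rng = np.random.default_rng(spec.seed)
    probs = spec.residue_probs()
    lo, hi = spec.protein_length
    fasta = io.StringIO()
    grouping = io.StringIO()
    proteins: dict[str, tuple[str, str]] = {}
    for b in range(spec.n_bins):
        label = f"bin{b:03d}"
        for p in range(spec.proteins_per_bin):
            pid = f"{label}_prot{p:02d}"
            seq = _random_protein(rng, int(rng.integers(lo, hi + 1)), probs)
            fasta.write(f">{pid} synthetic protein\n")
            for i in range(0, len(seq), 60):
                fasta.write(seq[i : i + 60] + "\n")
            grouping.write(f"{pid}\t{label}\n")
            proteins[pid] = (label, seq)
    return ReferenceFixture(
        fasta_text=fasta.getvalue(),
        grouping_text=grouping.getvalue(),
        proteins=proteins,
    )


def cleave(protein: str) -> list[str]:
    """Tryptic cleavage: cut after K or R except before P. No length
    filter; fragments concatenate back to the input."""
    fragments: list[str] = []
    start = 0
    for i, aa in enumerate(protein):
        if aa in "KR" and (i + 1 == len(protein) or protein[i + 1] != "P"):
            fragments.append(protein[start : i + 1])
            start = i + 1
    if start < len(protein):
        fragments.append(protein[start:])
    return fragments


def digest(
    protein: str,
    min_length: int = MIN_TRYPTIC_LENGTH,
    max_length: int = MAX_TRYPTIC_LENGTH,
) -> list[str]:
    """Tryptic peptides within the detectable length range (5-30 residues
    by default, the usual MS-observable span)."""
    return [f for f in cleave(protein) if min_length <= len(f) <= max_length]


def _positive_substitutions(model: SubstitutionModel) -> dict[str, list[str]]:
    """For each residue, the distinct replacements with score >= 0."""
    out: dict[str, list[str]] = {}
    for a in CANONICAL_ALPHABET:
        out[a] = [
            b
            for b in CANONICAL_ALPHABET
            if b != a and model.score(a, b) >= 0
        ]
    return out


def generate_queries(
    spec: FixtureSpec,
    reference: ReferenceFixture,
    model: SubstitutionModel | None = None,
) -> QueryFixture:
    """Sample query peptides with known origins.

    Target peptides are drawn from the tryptic digests of the configured
    source bins; with probability ``substitution_rate`` a single residue is
    replaced by a different residue scoring >= 0 against it in BLOSUM62
    (the kind of conservative exchange both de novo errors and true
    variants favour). ``decoy_fraction`` of the output is random-composition
    peptides belonging to no bin. Confidence scores are Beta-distributed.
    """
    rng = np.random.default_rng(spec.seed + 1)
    if model is None:
        model = load_blosum62()
    subs = _positive_substitutions(model)

    pool: list[tuple[str, str]] = []  # (bin label, peptide)
    wanted = set(spec.source_bins) if spec.source_bins is not None else None
    for label, seq in reference.proteins.values():
        if wanted is not None and label not in wanted:
            continue
        for pep in digest(seq, *spec.peptide_length):
            pool.append((label, pep))
    if not pool:
        raise ValueError("no tryptic peptides available from the source bins")

    n_decoy = int(round(spec.n_query_peptides * spec.decoy_fraction))
    n_target = spec.n_query_peptides - n_decoy
    replace = n_target > len(pool)
    idx = rng.choice(len(pool), size=n_target, replace=replace)

    alpha, beta = spec.confidence_beta
    probs = spec.residue_probs()
    rows = []
    for i in idx:
        label, pep = pool[i]
        mutated = False
        if spec.substitution_rate > 0 and rng.random() < spec.substitution_rate:
            pos_order = rng.permutation(len(pep))
            for pos in pos_order:
                choices = subs[pep[pos]]
                if choices:
                    repl = choices[int(rng.integers(len(choices)))]
                    pep = pep[:pos] + repl + pep[pos + 1 :]
                    mutated = True
                    break
        rows.append(
            {
                "peptide": pep,
                "confidence": float(np.clip(rng.beta(alpha, beta), 0.0, 1.0)),
                "origin": label,
                "mutated": mutated,
            }
        )
    lo, hi = spec.peptide_length
    for _ in range(n_decoy):
        length = int(rng.integers(lo, hi + 1))
        pep = "".join(rng.choice(list(CANONICAL_ALPHABET), size=length, p=probs))
        rows.append(
            {
                "peptide": pep,
                "confidence": float(np.clip(rng.beta(alpha, beta), 0.0, 1.0)),
                "origin": "decoy",
                "mutated": False,
            }
        )

    truth = pd.DataFrame(rows)
    peptides_text = "".join(
        f"{r['peptide']}\t{r['confidence']:.6f}\n" for r in rows
    )
    truth_text = "".join(
        f"{r['peptide']}\t{r['origin']}\t{int(r['mutated'])}\n" for r in rows
    )
    return QueryFixture(
        peptides_text=peptides_text, truth_text=truth_text, truth=truth
    )
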