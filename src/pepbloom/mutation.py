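"""Error-tolerant k-mer neighbourhood generation from substitution scores.

To tolerate amino-acid substitutions (sequencing errors, genuine variants),
every reference k-mer can be expanded at index-build time into the set of
variants whose cumulative substitution score

    score(v) = sum_i S(kmer_i, v_i)

meets a user-defined threshold, with S a symmetric 20x20 substitution
matrix (BLOSUM62 by default). Naively this evaluates up to 20**k variant
combinations; the enumeration here pre-sorts, for each residue, the 20
candidate replacements by descending score and prunes depth-first branches
whose optimistic completion (partial score plus the per-position maxima of
the remaining positions) cannot reach the threshold. With the sorted
candidate order, the first candidate that fails the bound at a given depth
guarantees all later candidates fail too, so the whole sibling range is cut.

The original k-mer is always part of the output, even when its self-score
is below the threshold, so unmutated reference sequences always remain
queryable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .kmer import CANONICAL_ALPHABET, NonCanonicalResidueError


@dataclass(frozen=True)
class MutationConfig:
    """Switch and threshold for index-time variant expansion."""

    enabled: bool = False
    score_threshold: int = 25


class SubstitutionModel:
    """Symmetric integer substitution scores over the canonical alphabet,
    plus per-residue candidate lists sorted by descending score (ties
    broken alphabetically, for reproducible enumeration order)."""

    def __init__(self, scores: dict[tuple[str, str], int]):
        for a in CANONICAL_ALPHABET:
            for b in CANONICAL_ALPHABET:
                if (a, b) not in scores:
                    raise ValueError(f"missing score for pair ({a}, {b})")
                if scores[(a, b)] != scores[(b, a)]:
                    raise ValueError(
                        f"asymmetric matrix: S({a},{b})={scores[(a, b)]} "
                        f"!= S({b},{a})={scores[(b, a)]}"
                    )
        self.scores = {
            (a, b): scores[(a, b)]
            for a in CANONICAL_ALPHABET
            for b in CANONICAL_ALPHABET
        }
        self.sorted_candidates = {
            a: sorted(CANONICAL_ALPHABET, key=lambda b: (-self.scores[(a, b)], b))
            for a in CANONICAL_ALPHABET
        }
        self.max_score = {
            a: self.scores[(a, self.sorted_candidates[a][0])]
            for a in CANONICAL_ALPHABET
        }

    def score(self, a: str, b: str) -> int:
        return self.scores[(a, b)]

    def self_score(self, kmer: str) -> int:
        return sum(self.scores[(aa, aa)] for aa in kmer)


def load_matrix(matrix_text: str) -> SubstitutionModel:
    """Parse a substitution matrix in the standard NCBI text layout.

    Expects a header row of residue symbols and one scored row per residue;
    ``#`` comment lines are skipped and non-canonical symbols (B, Z, X, *)
    are ignored. All 20 canonical residues must be present.
    """
    header: list[str] | None = None
    scores: dict[tuple[str, str], int] = {}
    seen_rows: set[str] = set()
    for line in matrix_text.splitlines():
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if header is None:
            header = parts
            continue
        row = parts[0]
        if row not in CANONICAL_ALPHABET:
            continue
        seen_rows.add(row)
        if len(parts) != len(header) + 1:
            raise ValueError(f"row {row!r} has {len(parts) - 1} values, "
                             f"expected {len(header)}")
        for col, value in zip(header, parts[1:]):
            if col in CANONICAL_ALPHABET:
                scores[(row, col)] = int(value)
    if header is None:
        raise ValueError("no header row found in matrix text")
    missing = set(CANONICAL_ALPHABET) - seen_rows
    if missing:
        raise ValueError(
            f"matrix is missing canonical residue rows: {sorted(missing)}"
        )
    return SubstitutionModel(scores)


def load_blosum62() -> SubstitutionModel:
    """The bundled BLOSUM62 matrix (half-bit log-odds, 62% clustering)."""
    text = (
        resources.files("pepbloom").joinpath("data/blosum62.txt").read_text()
    )
    return load_matrix(text)


def generate_variants(
    kmer: str, model: SubstitutionModel, threshold: int
) -> set[str]:
    """All variants of ``kmer`` with cumulative score >= ``threshold``,
    plus the original k-mer unconditionally."""
    variants, _ = _generate_variants_counted(kmer, model, threshold)
    return variants


def _generate_variants_counted(
    kmer: str, model: SubstitutionModel, threshold: int
) -> tuple[set[str], int]:
    """As :func:`generate_variants`, also returning the number of candidate
    nodes visited by the pruned search (for instrumentation)."""
    for i, aa in enumerate(kmer):
        if aa not in model.max_score:
            raise NonCanonicalResidueError(
                f"non-canonical residue {aa!r} at position {i} in {kmer!r}"
            )
    k = len(kmer)
    # best achievable score for the suffix starting at position d
    suffix_best = [0] * (k + 1)
    for d in range(k - 1, -1, -1):
        suffix_best[d] = suffix_best[d + 1] + model.max_score[kmer[d]]

    out: set[str] = set()
    visited = 0
    prefix = [""] * k

    def dfs(d: int, partial: int) -> None:
        nonlocal visited
        if d == k:
            out.add("".join(prefix))
            return
        orig = kmer[d]
        for cand in model.sorted_candidates[orig]:
            visited += 1
            score = partial + model.scores[(orig, cand)]
            if score + suffix_best[d + 1] < threshold:
                # candidates are sorted by descending score: every
                # remaining sibling fails the bound as well
                break
            prefix[d] = cand
            dfs(d + 1, score)

    dfs(0, 0)
    out.add(kmer)
    return out, visited


def expand_bin(
    kmers: Iterable[str], model: SubstitutionModel, config: MutationConfig
) -> set[str]:
    """Union of variant neighbourhoods over a bin's k-mers; a superset of
    the input. Identity when expansion is disabled."""
    kmers = set(kmers)
    if not config.enabled:
        return kmers
    out: set[str] = set()
    for km in kmers:
        out |= generate_variants(km, model, config.score_threshold)
    return out
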