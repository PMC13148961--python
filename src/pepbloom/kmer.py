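"""Amino-acid k-merization, 64-bit integer encoding, and forward minimizers.

Protein sequences are decomposed into overlapping k-mers over the 20-letter
canonical alphabet. Each k-mer is packed into a single unsigned 64-bit
integer using 5 bits per residue (alphabetical ordinals, first residue most
significant), which caps k at 12. Windows containing ambiguous residues
(X, B, Z, U, O, J, ``*``) are skipped rather than failing the whole
sequence. Minimizer sketching, when enabled, selects the numerically
smallest code in every window of consecutive k-mers — forward strand only,
since proteins have no reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: residue -> 5-bit ordinal, A=0 ... Y=19 (alphabetical)
RESIDUE_ORD = {aa: i for i, aa in enumerate(CANONICAL_ALPHABET)}

_BITS_PER_RESIDUE = 5
_BASE = 1 << _BITS_PER_RESIDUE  # 32
MAX_K = 12  # 12 residues * 5 bits = 60 bits <= 64


class NonCanonicalResidueError(ValueError):
    """A residue outside the 20-letter canonical alphabet was encountered."""


@dataclass(frozen=True)
class KmerConfig:
    """K-merization parameters shared by index build and query.

    Parameters
    ----------
    k : int
        k-mer length in residues; 1 <= k <= 12.
    minimizer_window : int
        Number of consecutive k-mers per minimizer window; 0 disables
        minimizer sketching, otherwise must be >= 2.
    collapse_il : bool
        Map isoleucine to leucine before k-merization. De novo sequencing
        cannot distinguish the isobaric pair; off by default.
    """

    k: int = 5
    minimizer_window: int = 0
    collapse_il: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.k <= MAX_K):
            raise ValueError(f"k must be in [1, {MAX_K}], got {self.k}")
        if self.minimizer_window != 0 and self.minimizer_window < 2:
            raise ValueError(
                f"minimizer_window must be 0 or >= 2, got {self.minimizer_window}"
            )


def _normalize(sequence: str, config: KmerConfig) -> str:
    sequence = sequence.upper()
    if config.collapse_il:
        sequence = sequence.replace("I", "L")
    return sequence


def kmerize(
    sequence: str, config: KmerConfig
) -> tuple[list[tuple[int, str]], int]:
    """Slide a length-k window over ``sequence``, keeping canonical windows.

    Returns ``(kmers, skipped)`` where ``kmers`` is an ordered list of
    ``(position, kmer)`` with 0-based positions and ``skipped`` counts
    windows dropped because they contained a non-canonical residue.
    Sequences shorter than k yield an empty list.
    """
    sequence = _normalize(sequence, config)
    k = config.k
    kmers: list[tuple[int, str]] = []
    skipped = 0
    # positions of non-canonical residues; a window is valid iff it
    # contains none of them
    bad = [i for i, aa in enumerate(sequence) if aa not in RESIDUE_ORD]
    bad_iter = iter(bad + [len(sequence) + k])
    next_bad = next(bad_iter)
    for pos in range(len(sequence) - k + 1):
        while next_bad < pos:
            next_bad = next(bad_iter)
        if next_bad < pos + k:
            skipped += 1
        else:
            kmers.append((pos, sequence[pos : pos + k]))
    return kmers, skipped


def encode(kmer: str, config: KmerConfig) -> int:
    """Pack a k-mer into one unsigned 64-bit integer.

    ``code = sum(ord(residue_i) * 32**(k-1-i))`` with alphabetical ordinals;
    the first residue is most significant, so codes of equal length compare
    like the underlying strings.
    """
    if len(kmer) != config.k:
        raise ValueError(f"expected a {config.k}-mer, got {kmer!r}")
    code = 0
    for i, aa in enumerate(kmer):
        try:
            code = (code << _BITS_PER_RESIDUE) | RESIDUE_ORD[aa]
        except KeyError:
            raise NonCanonicalResidueError(
                f"non-canonical residue {aa!r} at position {i} in {kmer!r}"
            ) from None
    return code


def decode(code: int, config: KmerConfig) -> str:
    """Inverse of :func:`encode` for the configured k."""
    if not (0 <= code < _BASE**config.k):
        raise ValueError(f"code {code} out of range for k={config.k}")
    residues = []
    for _ in range(config.k):
        residues.append(CANONICAL_ALPHABET[code & (_BASE - 1)])
        code >>= _BITS_PER_RESIDUE
    return "".join(reversed(residues))


def encode_sequence(sequence: str, config: KmerConfig) -> list[int]:
    """Ordered encoded k-mers of a sequence (ambiguous windows skipped)."""
    kmers, _ = kmerize(sequence, config)
    return [encode(km, config) for _, km in kmers]


def minimizers(kmers: Sequence[int], window: int) -> set[int]:
    """Forward-strand minimizers over windows of ``window`` consecutive k-mers.

    For every run of ``window`` consecutive codes the numerically smallest
    is selected; the union of selections is returned. Fewer codes than one
    window form a single window. Ordering is plain numeric order of the
    64-bit code — deterministic, no hash shuffling.
    """
    if window < 2:
        raise ValueError(f"minimizer window must be >= 2, got {window}")
    if not kmers:
        return set()
    if len(kmers) <= window:
        return {min(kmers)}
    return {min(kmers[i : i + window]) for i in range(len(kmers) - window + 1)}


def sketch(sequence: str, config: KmerConfig) -> set[int]:
    """Distinct encoded k-mers of a sequence, minimizer-reduced if enabled."""
    codes = encode_sequence(sequence, config)
    if config.minimizer_window:
        return minimizers(codes, config.minimizer_window)
    return set(codes)


def sketch_many(sequences: Iterable[str], config: KmerConfig) -> set[int]:
    """Union of :func:`sketch` over several sequences."""
    out: set[int] = set()
    for seq in sequences:
        out |= sketch(seq, config)
    return out
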