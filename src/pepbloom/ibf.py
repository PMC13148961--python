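"""Bloom-filter sizing mathematics and the interleaved Bloom filter (IBF).

An IBF packs *b* equally sized Bloom filters (one per user bin) into a
single bit matrix of shape ``(n, b)``: each of the *n* bit positions holds
a *b*-bit sub-vector, so one hash probe answers membership for every bin at
once. All bins share the same H hash functions.

The false-positive rate of one bin holding *m* elements is

    p = (1 - (1 - 1/n)**(H*m))**H

and the minimal per-bin size for a target rate p at load ``max_kmers`` is

    n = ceil(-1 / (r**(1/(H*max_kmers)) - 1)),   r = 1 - p**(1/H).

The H hash functions are realised as one 64-bit avalanche mix (the
splitmix64 finalizer) applied to ``code XOR seed`` with H fixed distinct
seeds recorded alongside the filter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

DEFAULT_FPR = 0.01
DEFAULT_HASH_COUNT = 3

_U64 = np.uint64
_MASK64 = 0xFFFFFFFFFFFFFFFF


def false_positive_rate(n: int, m: int, hash_count: int) -> float:
    """Predicted false-positive probability of one bin (size n bits, m
    inserted elements, ``hash_count`` hash functions)."""
    if n < 1:
        raise ValueError("bin size n must be >= 1")
    if m < 0 or hash_count < 1:
        raise ValueError("need m >= 0 and hash_count >= 1")
    if m == 0:
        return 0.0
    return (1.0 - (1.0 - 1.0 / n) ** (hash_count * m)) ** hash_count


def optimal_bin_size(max_kmers: int, target_fpr: float, hash_count: int) -> int:
    """Bits per bin needed to keep the rate at or below ``target_fpr`` when
    holding ``max_kmers`` distinct elements.

    ``max_kmers = 0`` (an empty bin) returns 1 by convention.
    """
    if not (0.0 < target_fpr < 1.0):
        raise ValueError(f"target_fpr must be in (0, 1), got {target_fpr}")
    if max_kmers < 0:
        raise ValueError("max_kmers must be >= 0")
    if max_kmers == 0:
        return 1
    r = 1.0 - target_fpr ** (1.0 / hash_count)
    return math.ceil(-1.0 / (r ** (1.0 / (hash_count * max_kmers)) - 1.0))


@dataclass(frozen=True)
class BloomParams:
    """Sizing parameters of one IBF (shared by all its bins)."""

    target_fpr: float = DEFAULT_FPR
    hash_count: int = DEFAULT_HASH_COUNT
    max_kmers: int = 0
    bits_per_bin: int = 1

    @classmethod
    def from_load(
        cls,
        max_kmers: int,
        target_fpr: float = DEFAULT_FPR,
        hash_count: int = DEFAULT_HASH_COUNT,
    ) -> "BloomParams":
        """Size a filter from its expected load."""
        n = optimal_bin_size(max_kmers, target_fpr, hash_count)
        return cls(
            target_fpr=target_fpr,
            hash_count=hash_count,
            max_kmers=max_kmers,
            bits_per_bin=n,
        )


def _splitmix64(x: np.ndarray) -> np.ndarray:
    z = (x + _U64(0x9E3779B97F4A7C15)) & _U64(_MASK64)
    z = ((z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)) & _U64(_MASK64)
    z = ((z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)) & _U64(_MASK64)
    return z ^ (z >> _U64(31))


def make_hash_seeds(hash_count: int, base_seed: int = 0x5EEDB100F) -> list[int]:
    """H distinct 64-bit seeds derived deterministically from ``base_seed``."""
    stream = _splitmix64(
        np.arange(1, hash_count + 1, dtype=_U64) + _U64(base_seed & _MASK64)
    )
    return [int(s) for s in stream]


def hash_positions(codes: np.ndarray, seeds: list[int], n: int) -> np.ndarray:
    """Probe positions, shape (len(codes), H): splitmix64(code ^ seed) mod n."""
    codes = np.asarray(codes, dtype=_U64).reshape(-1, 1)
    seed_row = np.array(seeds, dtype=_U64).reshape(1, -1)
    with np.errstate(over="ignore"):
        return (_splitmix64(codes ^ seed_row) % _U64(n)).astype(np.int64)


@dataclass
class InterleavedBloomFilter:
    """Bit matrix of shape (bits_per_bin, bin_count), position-major."""

    params: BloomParams
    bin_labels: list[str]
    hash_seeds: list[int] = field(default_factory=lambda: make_hash_seeds(3))
    bits: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(set(self.bin_labels)) != len(self.bin_labels):
            raise ValueError("bin labels must be unique")
        if len(self.hash_seeds) != self.params.hash_count:
            raise ValueError("need one hash seed per hash function")
        if self.bits is None:
            self.bits = np.zeros(
                (self.params.bits_per_bin, self.bin_count), dtype=bool
            )

    @property
    def bin_count(self) -> int:
        return len(self.bin_labels)

    def insert(self, bin_index: int, codes) -> None:
        """Insert encoded k-mers into one bin. Idempotent."""
        if not (0 <= bin_index < self.bin_count):
            raise IndexError(
                f"bin index {bin_index} out of range [0, {self.bin_count})"
            )
        codes = np.fromiter(codes, dtype=_U64) if not isinstance(
            codes, np.ndarray
        ) else codes.astype(_U64)
        if codes.size == 0:
            return
        pos = hash_positions(codes, self.hash_seeds, self.params.bits_per_bin)
        self.bits[pos.ravel(), bin_index] = True

    def query_counts(self, codes) -> np.ndarray:
        """Per-bin count of query k-mers present (all H probed bits set).

        ``codes`` should be deduplicated; each distinct k-mer contributes at
        most one count per bin. Returns an integer vector of length b.
        """
        codes = np.fromiter(set(codes), dtype=_U64)
        if codes.size == 0:
            return np.zeros(self.bin_count, dtype=np.int64)
        pos = hash_positions(codes, self.hash_seeds, self.params.bits_per_bin)
        # (q, H, b) -> all probes set -> (q, b) membership
        member = self.bits[pos, :].all(axis=1)
        return member.sum(axis=0, dtype=np.int64)

    def contains(self, code: int, bin_index: int) -> bool:
        return bool(self.query_counts([code])[bin_index])

    # -- serialization ----------------------------------------------------

    def to_arrays(self) -> dict[str, np.ndarray]:
        header = {
            "target_fpr": self.params.target_fpr,
            "hash_count": self.params.hash_count,
            "max_kmers": self.params.max_kmers,
            "bits_per_bin": self.params.bits_per_bin,
            "bin_labels": self.bin_labels,
            "hash_seeds": self.hash_seeds,
        }
        return {
            "header": np.frombuffer(
                json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
            ),
            "bits": np.packbits(self.bits, axis=0),
        }

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray]) -> "InterleavedBloomFilter":
        header = json.loads(bytes(arrays["header"]).decode())
        n = header["bits_per_bin"]
        bits = np.unpackbits(arrays["bits"], axis=0, count=n).astype(bool)
        return cls(
            params=BloomParams(
                target_fpr=header["target_fpr"],
                hash_count=header["hash_count"],
                max_kmers=header["max_kmers"],
                bits_per_bin=n,
            ),
            bin_labels=list(header["bin_labels"]),
            hash_seeds=[int(s) for s in header["hash_seeds"]],
            bits=bits,
        )

    def save(self, path) -> None:
        np.savez(path, **self.to_arrays())

    @classmethod
    def load(cls, path) -> "InterleavedBloomFilter":
        with np.load(path) as data:
            return cls.from_arrays({k: data[k] for k in data.files})
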