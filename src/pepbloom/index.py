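"""Multi-index construction: batched IBFs over user-defined reference bins.

Large reference databases are handled divide-and-conquer style: user bins
(proteins, proteomes or taxa) are partitioned, in input order, into batches
of at most ``split_size`` bins; each batch becomes one independently sized
IBF. Per-batch sizing keeps every filter only as large as its own heaviest
bin requires (the ``maxKmers`` load), instead of paying the global maximum
across the whole database. A blacklist removes over-represented or
otherwise unwanted references before batching. The ordered collection of
IBFs plus a global bin directory forms the multi-index, which queries
exactly like one monolithic IBF.
"""

from __future__ import annotations

import hashlib
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from . import __version__
from .ibf import (
    DEFAULT_FPR,
    DEFAULT_HASH_COUNT,
    BloomParams,
    InterleavedBloomFilter,
    make_hash_seeds,
)
from .kmer import KmerConfig, encode, kmerize, minimizers
from .mutation import MutationConfig, SubstitutionModel, expand_bin, load_blosum62

DEFAULT_SPLIT_SIZE = 64

FORMAT_VERSION = 1


@dataclass
class UserBin:
    """One reference entity occupying one IBF column."""

    label: str
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("bin label must be non-empty")


@dataclass(frozen=True)
class BuildConfig:
    kmer: KmerConfig = KmerConfig()
    target_fpr: float = DEFAULT_FPR
    hash_count: int = DEFAULT_HASH_COUNT
    split_size: int = DEFAULT_SPLIT_SIZE
    mutation: MutationConfig = MutationConfig()
    hash_seed: int = 0x5EEDB100F
    blacklist_digest: str = ""

    def hash_seeds(self) -> list[int]:
        return make_hash_seeds(self.hash_count, self.hash_seed)


def load_bins(
    fasta: str | Path | io.TextIOBase, grouping: str | Path | None = None
) -> list[UserBin]:
    """Load reference bins from a protein FASTA, optionally merged by a
    grouping table.

    Without grouping every record is its own bin, labelled by the first
    whitespace-delimited token of its header. A grouping TSV
    (``record_id<TAB>bin_label``, no header) merges records that share a
    label into one multi-sequence bin; records absent from the table fall
    back to singleton bins with a warning, and table rows naming unknown
    records are ignored with a warning.
    """
    records = list(SeqIO.parse(fasta, "fasta"))
    if not records:
        raise ValueError("no records parsed from FASTA input")
    ids = [rec.id for rec in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate record IDs in FASTA: {dupes}")

    mapping: dict[str, str] = {}
    if grouping is not None:
        with open(grouping) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(
                        f"grouping line {lineno}: expected 2 tab-separated "
                        f"fields, got {len(parts)}"
                    )
                mapping[parts[0]] = parts[1]
        unknown = set(mapping) - set(ids)
        if unknown:
            warnings.warn(
                f"grouping references {len(unknown)} unknown record ID(s), "
                f"ignored: {sorted(unknown)[:5]}"
            )

    bins: dict[str, UserBin] = {}
    order: list[str] = []
    for rec in records:
        if grouping is not None and rec.id not in mapping:
            warnings.warn(
                f"record {rec.id!r} absent from grouping table; "
                "kept as a singleton bin"
            )
        label = mapping.get(rec.id, rec.id)
        if label not in bins:
            bins[label] = UserBin(label=label)
            order.append(label)
        bins[label].sequences.append(str(rec.seq))
    return [bins[label] for label in order]


def read_blacklist(path: str | Path) -> set[str]:
    """Labels to exclude, one per line; ``#`` comments and blanks skipped."""
    labels: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                labels.add(line)
    return labels


def blacklist_digest(labels: set[str]) -> str:
    if not labels:
        return ""
    joined = "\n".join(sorted(labels)).encode()
    return hashlib.sha256(joined).hexdigest()


def plan_splits(
    bins: list[UserBin], split_size: int, blacklist: set[str] | None = None
) -> list[list[UserBin]]:
    """Drop blacklisted bins, then chunk the rest (input order preserved)
    into batches of ``split_size``; the last batch holds the remainder."""
    if split_size < 1:
        raise ValueError("split_size must be >= 1")
    blacklist = blacklist or set()
    kept = [b for b in bins if b.label not in blacklist]
    if not kept:
        raise ValueError("empty index: every bin is blacklisted")
    return [kept[i : i + split_size] for i in range(0, len(kept), split_size)]


def bin_kmer_codes(
    user_bin: UserBin,
    kconfig: KmerConfig,
    model: SubstitutionModel | None = None,
    mconfig: MutationConfig | None = None,
) -> set[int]:
    """Distinct encoded k-mers a bin contributes to its IBF column.

    Per sequence: k-merize, then (if enabled) reduce to forward minimizers
    over the ordered original k-mers; the union over sequences is then
    mutation-expanded (if enabled) so the filter holds original and variant
    k-mers alike.
    """
    selected: set[str] = set()
    for seq in user_bin.sequences:
        kmers, _ = kmerize(seq, kconfig)
        if not kmers:
            continue
        strings = [km for _, km in kmers]
        if kconfig.minimizer_window:
            codes = [encode(km, kconfig) for km in strings]
            keep = minimizers(codes, kconfig.minimizer_window)
            selected |= {km for km, c in zip(strings, codes) if c in keep}
        else:
            selected |= set(strings)
    if mconfig is not None and mconfig.enabled:
        if model is None:
            model = load_blosum62()
        selected = expand_bin(selected, model, mconfig)
    return {encode(km, kconfig) for km in selected}


def estimate_max_kmers(
    batch: list[UserBin],
    kconfig: KmerConfig,
    model: SubstitutionModel | None = None,
    mconfig: MutationConfig | None = None,
) -> int:
    """The batch's sizing load: largest distinct-k-mer count over its bins
    (after expansion/minimization), floored at 1 so empty bins still size."""
    if not batch:
        raise ValueError("batch must be non-empty")
    counts = [len(bin_kmer_codes(b, kconfig, model, mconfig)) for b in batch]
    return max(1, max(counts))


@dataclass
class MultiIndex:
    """Ordered IBFs over disjoint batches of user bins, plus metadata."""

    ibfs: list[InterleavedBloomFilter]
    config: BuildConfig

    @property
    def bin_labels(self) -> list[str]:
        return [label for ibf in self.ibfs for label in ibf.bin_labels]

    @property
    def bin_directory(self) -> dict[str, tuple[int, int]]:
        """bin label -> (ibf index, local bin index)."""
        out: dict[str, tuple[int, int]] = {}
        for i, ibf in enumerate(self.ibfs):
            for j, label in enumerate(ibf.bin_labels):
                out[label] = (i, j)
        return out

    @property
    def bin_count(self) -> int:
        return sum(ibf.bin_count for ibf in self.ibfs)

    def query_counts(self, codes) -> np.ndarray:
        """Global per-bin membership counts: per-IBF counting queries
        concatenated in bin-directory order."""
        if not self.ibfs:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate([ibf.query_counts(codes) for ibf in self.ibfs])

    # -- serialization ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        header = {
            "format_version": FORMAT_VERSION,
            "tool_version": __version__,
            "n_ibfs": len(self.ibfs),
            "k": self.config.kmer.k,
            "minimizer_window": self.config.kmer.minimizer_window,
            "collapse_il": self.config.kmer.collapse_il,
            "target_fpr": self.config.target_fpr,
            "hash_count": self.config.hash_count,
            "split_size": self.config.split_size,
            "mutation_enabled": self.config.mutation.enabled,
            "mutation_threshold": self.config.mutation.score_threshold,
            "hash_seed": self.config.hash_seed,
            "blacklist_digest": self.config.blacklist_digest,
        }
        arrays["header"] = np.frombuffer(
            json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
        )
        for i, ibf in enumerate(self.ibfs):
            for key, arr in ibf.to_arrays().items():
                arrays[f"ibf{i}_{key}"] = arr
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "MultiIndex":
        with np.load(path) as data:
            header = json.loads(bytes(data["header"]).decode())
            if header["format_version"] != FORMAT_VERSION:
                raise ValueError(
                    f"unsupported index format version "
                    f"{header['format_version']}"
                )
            ibfs = [
                InterleavedBloomFilter.from_arrays(
                    {
                        "header": data[f"ibf{i}_header"],
                        "bits": data[f"ibf{i}_bits"],
                    }
                )
                for i in range(header["n_ibfs"])
            ]
        config = BuildConfig(
            kmer=KmerConfig(
                k=header["k"],
                minimizer_window=header["minimizer_window"],
                collapse_il=header["collapse_il"],
            ),
            target_fpr=header["target_fpr"],
            hash_count=header["hash_count"],
            split_size=header["split_size"],
            mutation=MutationConfig(
                enabled=header["mutation_enabled"],
                score_threshold=header["mutation_threshold"],
            ),
            hash_seed=header["hash_seed"],
            blacklist_digest=header["blacklist_digest"],
        )
        return cls(ibfs=ibfs, config=config)


def build_index(
    bins: list[UserBin],
    config: BuildConfig = BuildConfig(),
    blacklist: set[str] | None = None,
    model: SubstitutionModel | None = None,
) -> MultiIndex:
    """Build a multi-index: blacklist, batch, size, populate.

    Deterministic for fixed inputs and configuration (hash seeds derive
    from ``config.hash_seed``): rebuilding yields a byte-identical archive.
    Bins with no valid k-mers are retained (with a warning) so bin indices
    stay aligned with the input; they simply never match anything.
    """
    blacklist = blacklist or set()
    config = BuildConfig(
        kmer=config.kmer,
        target_fpr=config.target_fpr,
        hash_count=config.hash_count,
        split_size=config.split_size,
        mutation=config.mutation,
        hash_seed=config.hash_seed,
        blacklist_digest=blacklist_digest(blacklist),
    )
    if config.mutation.enabled and model is None:
        model = load_blosum62()
    seeds = config.hash_seeds()
    batches = plan_splits(bins, config.split_size, blacklist)
    ibfs: list[InterleavedBloomFilter] = []
    for batch in batches:
        codes_per_bin = [
            bin_kmer_codes(b, config.kmer, model, config.mutation)
            for b in batch
        ]
        for b, codes in zip(batch, codes_per_bin):
            if not codes:
                warnings.warn(
                    f"bin {b.label!r} contributes no valid k-mers; retained "
                    "as an empty column"
                )
        load = max(1, max(len(c) for c in codes_per_bin))
        params = BloomParams.from_load(
            load, config.target_fpr, config.hash_count
        )
        ibf = InterleavedBloomFilter(
            params=params,
            bin_labels=[b.label for b in batch],
            hash_seeds=seeds,
        )
        for j, codes in enumerate(codes_per_bin):
            ibf.insert(j, codes)
        ibfs.append(ibf)
    return MultiIndex(ibfs=ibfs, config=config)
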