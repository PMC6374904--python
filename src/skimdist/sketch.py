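"""Bottom-s MinHash sketching of k-mer sets and Jaccard estimation.

A sketch keeps the s smallest distinct 64-bit hash values of the retained
canonical k-mers (multiplicity >= m).  Two sketches with the same hash seed
give the merged-bottom Jaccard estimator: take the s smallest values of the
union of the two sketches and count how many occur in both — an unbiased
estimate of |A∩B|/|A∪B| for bottom sketches.

The hash is the splitmix64 finalizer applied to the 2-bit packed canonical
k-mer XOR a seed-derived constant; it is vectorised over numpy uint64 and
identical across platforms and runs, so sketches are reproducible and
comparable only when built with the same seed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .kmers import KmerTable

DEFAULT_SKETCH_SIZE = 10_000_000
DEFAULT_HASH_SEED = 42

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xBF58476D1CE4E5B9)
_MIX2 = np.uint64(0x94D049BB133111EB)


def hash_codes(codes: np.ndarray, seed: int) -> np.ndarray:
    """Seeded splitmix64 avalanche of packed k-mer codes (vectorised)."""
    seed_mix = np.uint64((int(seed) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF)
    z = codes.astype(np.uint64) ^ seed_mix
    z = (z + _GOLDEN)
    z = (z ^ (z >> np.uint64(30))) * _MIX1
    z = (z ^ (z >> np.uint64(27))) * _MIX2
    return z ^ (z >> np.uint64(31))


@dataclass
class Sketch:
    """Bottom-s sketch: sorted distinct hashes of retained canonical k-mers."""

    k: int
    s: int
    hash_seed: int
    hashes: np.ndarray          # sorted uint64, length <= s
    n_kmers_retained: int = 0

    def to_file(self, path: str | Path) -> None:
        """Gzipped text: header ``k s seed n`` then one hex hash per line."""
        with gzip.open(path, "wt") as fh:
            fh.write(f"{self.k} {self.s} {self.hash_seed} {self.n_kmers_retained}\n")
            for h in self.hashes:
                fh.write(f"{int(h):016x}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Sketch":
        with gzip.open(path, "rt") as fh:
            k, s, seed, n = (int(x) for x in fh.readline().split())
            hashes = np.array([int(line, 16) for line in fh], dtype=np.uint64)
        return cls(k=k, s=s, hash_seed=seed, hashes=hashes, n_kmers_retained=n)


def build_sketch(
    table: KmerTable,
    s: int = DEFAULT_SKETCH_SIZE,
    m: int = 1,
    hash_seed: int = DEFAULT_HASH_SEED,
) -> Sketch:
    """Sketch the k-mers of ``table`` with multiplicity >= m."""
    if s < 1:
        raise ValueError("sketch size must be >= 1")
    if m < 1:
        raise ValueError("minimum multiplicity must be >= 1")
    retained = table.codes[table.counts >= m]
    if retained.size == 0:
        raise ValueError("empty sketch: no k-mer passes the multiplicity filter")
    hashes = np.unique(hash_codes(retained, hash_seed))
    return Sketch(
        k=table.k, s=s, hash_seed=hash_seed,
        hashes=hashes[:s], n_kmers_retained=int(retained.size),
    )


def _check_compatible(a: Sketch, b: Sketch) -> None:
    if a.k != b.k:
        raise ValueError(f"sketch k mismatch: {a.k} != {b.k}")
    if a.hash_seed != b.hash_seed:
        raise ValueError(f"sketch hash seed mismatch: {a.hash_seed} != {b.hash_seed}")


def jaccard(a: Sketch, b: Sketch) -> float:
    """Merged-bottom Jaccard estimate between two sketches."""
    _check_compatible(a, b)
    union = np.union1d(a.hashes, b.hashes)
    s_eff = min(max(a.s, b.s), union.size)
    bottom = union[:s_eff]
    in_a = np.isin(bottom, a.hashes, assume_unique=True)
    in_b = np.isin(bottom, b.hashes, assume_unique=True)
    return float(np.count_nonzero(in_a & in_b)) / s_eff


def exact_jaccard(a: KmerTable, b: KmerTable, m_a: int = 1, m_b: int = 1) -> float:
    """Exact Jaccard of the retained distinct k-mer sets (testing oracle)."""
    if a.k != b.k:
        raise ValueError("k mismatch")
    set_a = a.codes[a.counts >= m_a]
    set_b = b.codes[b.counts >= m_b]
    if set_a.size == 0 and set_b.size == 0:
        raise ValueError("both k-mer sets empty after filtering")
    inter = np.intersect1d(set_a, set_b, assume_unique=True).size
    union = set_a.size + set_b.size - inter
    return inter / union
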