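"""Canonical k-mer counting and frequency histograms.

Reads are decomposed into overlapping windows of length ``k``; each window is
replaced by the lexicographic minimum of itself and its reverse complement
(the *canonical* k-mer), so that counts are strand-agnostic.  Counting is
exact.  The abundance histogram ``M[i]`` — the number of distinct canonical
k-mers seen exactly ``i`` times — is the sufficient statistic the coverage /
error estimator consumes.

k-mers are stored 2-bit packed in uint64 (A=0, C=1, G=2, T=3), which limits
``k`` to 32; windows containing any non-ACGT character are skipped.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

# byte -> 2-bit code; 255 marks invalid characters (uppercased first)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


# ---------------------------------------------------------------------------
# sequence input
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Summary statistics of a read set (or assembly) used downstream."""

    source_path: str
    n_reads: int
    total_bases: int
    mean_read_length: float
    is_assembly: bool = False


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    raw = open(path, "rb")
    if raw.read(2) == b"\x1f\x8b":
        raw.seek(0)
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw))
    raw.seek(0)
    return io.TextIOWrapper(raw)


def _sniff_format(handle: io.TextIOBase) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError("cannot determine sequence format (expected FASTA or FASTQ)")


def read_sequences(
    path: str | Path,
    format_hint: str = "auto",
    is_assembly: bool = False,
) -> tuple[ReadSet, list[str]]:
    """Load a FASTA/FASTQ file (optionally gzipped).

    Returns the per-file statistics and the list of sequences, uppercased,
    in file order.  Quality strings are ignored.
    """
    handle = _open_text(path)
    with handle:
        fmt = format_hint if format_hint in ("fasta", "fastq") else _sniff_format(handle)
        seqs: list[str] = []
        records = SeqIO.parse(handle, fmt)
        index = 0
        while True:
            try:
                rec = next(records)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed {fmt} record at index {index}: {exc}") from exc
            seqs.append(str(rec.seq).upper())
            index += 1
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    total = sum(len(s) for s in seqs)
    stats = ReadSet(
        source_path=str(path),
        n_reads=len(seqs),
        total_bases=total,
        mean_read_length=total / len(seqs),
        is_assembly=is_assembly,
    )
    return stats, seqs


def read_stats(
    seqs: Iterable[str], source: str = "<memory>", is_assembly: bool = False
) -> ReadSet:
    """ReadSet statistics for in-memory sequences (no file round trip)."""
    lengths = [len(s) for s in seqs]
    if not lengths:
        raise ValueError("no sequences")
    total = sum(lengths)
    return ReadSet(source, len(lengths), total, total / len(lengths), is_assembly)


# ---------------------------------------------------------------------------
# canonical k-mers
# ---------------------------------------------------------------------------

def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def encode_kmer(kmer: str) -> int:
    """2-bit pack a k-mer (A=0,C=1,G=2,T=3); big-endian in the integer."""
    code = 0
    for b in kmer:
        code = (code << 2) | _BASES.index(b)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(code >> shift) & 3])
    return "".join(out)


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical packed codes of all valid k-windows of a code array.

    ``codes`` uses 255 for invalid characters; any window touching one is
    dropped.  Vectorised: k passes over the array instead of one pass per
    window.
    """
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    nwin = n - k + 1
    valid = np.ones(nwin, dtype=bool)
    fwd = np.zeros(nwin, dtype=np.uint64)
    rev = np.zeros(nwin, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    bad = codes == 255
    for j in range(k):
        col = c64[j : j + nwin]
        valid &= ~bad[j : j + nwin]
        fwd |= (col & np.uint64(3)) << np.uint64(2 * (k - 1 - j))
        rev |= ((np.uint64(3) - (col & np.uint64(3)))) << np.uint64(2 * j)
    canon = np.minimum(fwd, rev)
    return canon[valid]


def canonical_kmers(sequence: str, k: int) -> list[str]:
    """Canonical k-mers of every ACGT-only window, in order of occurrence."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 32:
        raise ValueError("k > 32 not supported by the 2-bit packing")
    codes = _CODE[np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)]
    # order must follow the sequence; _window_codes preserves window order
    return [decode_kmer(int(c), k) for c in _window_codes(codes, k)]


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------

@dataclass
class KmerTable:
    """Exact multiplicities of canonical k-mers, array-backed.

    ``codes`` are the sorted 2-bit packed canonical k-mers, ``counts`` their
    multiplicities (aligned, all >= 1).
    """

    k: int
    codes: np.ndarray
    counts: np.ndarray

    @property
    def n_distinct(self) -> int:
        return int(self.codes.size)

    @property
    def n_instances(self) -> int:
        return int(self.counts.sum())

    def get(self, kmer: str, default: int = 0) -> int:
        code = np.uint64(encode_kmer(canonical(kmer)))
        i = np.searchsorted(self.codes, code)
        if i < self.codes.size and self.codes[i] == code:
            return int(self.counts[i])
        return default

    def items(self) -> Iterator[tuple[str, int]]:
        for code, cnt in zip(self.codes, self.counts):
            yield decode_kmer(int(code), self.k), int(cnt)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())

    @classmethod
    def from_dict(cls, counts: dict[str, int], k: int) -> "KmerTable":
        codes = np.array(sorted(encode_kmer(canonical(s)) for s in counts), dtype=np.uint64)
        cnts = np.array(
            [counts[s] for s in sorted(counts, key=lambda s: encode_kmer(canonical(s)))],
            dtype=np.int64,
        )
        if np.unique(codes).size != codes.size:
            raise ValueError("keys collide after canonicalization")
        return cls(k=k, codes=codes, counts=cnts)


def count_kmers(reads: Iterable[str], k: int) -> KmerTable:
    """Exact canonical k-mer counts over a collection of sequences.

    Sequences are concatenated with an ``N`` separator so the sliding-window
    pass is a single vectorised sweep; the separator invalidates every window
    that would straddle two reads.
    """
    if k < 1 or k > 32:
        raise ValueError("k must be in [1, 32]")
    reads = list(reads) if not isinstance(reads, list) else reads
    if not reads:
        raise ValueError("no sequences to count")
    if all(len(r) < k for r in reads):
        raise ValueError("k exceeds read length for every read")
    blob = "N".join(reads)
    codes = _CODE[np.frombuffer(blob.upper().encode("ascii"), dtype=np.uint8)]
    canon = _window_codes(codes, k)
    if canon.size == 0:
        raise ValueError("no valid k-mer windows (all windows contain non-ACGT)")
    uniq, counts = np.unique(canon, return_counts=True)
    return KmerTable(k=k, codes=uniq, counts=counts.astype(np.int64))


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------

@dataclass
class KmerHistogram:
    """Abundance spectrum: M[i] = number of distinct k-mers seen i times."""

    k: int
    M: dict[int, int] = field(default_factory=dict)
    n_distinct: int = 0
    n_instances: int = 0

    def __post_init__(self) -> None:
        if not self.n_distinct:
            self.n_distinct = sum(self.M.values())
        if not self.n_instances:
            self.n_instances = sum(i * m for i, m in self.M.items())

    def to_tsv(self, path: str | Path) -> None:
        """Two-column TSV, ``abundance<TAB>count``, ascending abundance."""
        with open(path, "w") as fh:
            for i in sorted(self.M):
                fh.write(f"{i}\t{self.M[i]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int) -> "KmerHistogram":
        M: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    i, m = line.split("\t")
                    M[int(i)] = int(m)
        return cls(k=k, M=M)


def histogram(table: KmerTable) -> KmerHistogram:
    """Abundance histogram of a k-mer table."""
    if table.n_distinct == 0:
        raise ValueError("empty k-mer table")
    abund, n = np.unique(table.counts, return_counts=True)
    return KmerHistogram(
        k=table.k,
        M={int(a): int(c) for a, c in zip(abund, n)},
        n_distinct=table.n_distinct,
        n_instances=table.n_instances,
    )
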