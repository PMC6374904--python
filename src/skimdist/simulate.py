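"""Synthetic genomes and genome skims with controlled distance.

The generator mirrors the controlled-mutation experiment the estimator is
designed for: a random (or supplied) genome, a mutated copy with single
nucleotide substitutions placed uniformly at random at rate ``d``, and skims
of short reads with uniform start positions and a flat per-base substitution
error rate.  Reads carry no indels and no positional quality model — the
coverage/error estimator assumes a constant miscall rate, so the fixture
realises exactly that model; robustness to position-dependent error can be
probed through the ``error_profile`` hook of :func:`sample_reads`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class SimConfig:
    """Conditions of one controlled-distance skim pair."""

    genome_length: int = 1_000_000
    distance: float = 0.05
    coverage: float = 1.0
    read_length: int = 100
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.distance <= 0.3:
            raise ValueError("distance must be in [0, 0.3]")
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error rate must be in [0, 0.1]")
        if min(self.genome_length, self.read_length) < 1 or self.coverage <= 0:
            raise ValueError("sizes and coverage must be positive")


def _to_codes(genome: str) -> np.ndarray:
    codes = _CODE[np.frombuffer(genome.upper().encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("genome contains non-ACGT characters")
    return codes


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def random_genome(length: int, seed: int | np.random.Generator) -> str:
    """Uniform i.i.d. ACGT sequence, deterministic given the seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    return _to_str(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate_genome(genome: str, d: float, seed: int | np.random.Generator) -> str:
    """Substitute each site with probability d, uniformly to another base."""
    if not 0 <= d < 0.75:
        raise ValueError("d must be in [0, 0.75)")
    rng = np.random.default_rng(seed)
    codes = _to_codes(genome).copy()
    hit = np.flatnonzero(rng.random(codes.size) < d)
    shift = rng.integers(1, 4, size=hit.size, dtype=np.uint8)
    codes[hit] = (codes[hit] + shift) % 4
    return _to_str(codes)


def sample_reads(
    genome: str,
    coverage: float,
    read_length: int,
    error_rate: float,
    seed: int | np.random.Generator,
    random_strand: bool = False,
    error_profile: Callable[[int], np.ndarray] | None = None,
) -> list[str]:
    """Skim a genome: uniform read starts, flat substitution errors.

    ``error_profile(read_length)`` may supply a per-position error rate
    vector overriding the flat ``error_rate``.  Reads come from the forward
    strand unless ``random_strand`` is set (canonical k-mer counting is
    strand-invariant either way).
    """
    codes = _to_codes(genome)
    L = codes.size
    if read_length > L:
        raise ValueError("read length exceeds genome length")
    rng = np.random.default_rng(seed)
    n = int(round(coverage * L / read_length))
    starts = rng.integers(0, L - read_length + 1, size=n)
    reads = codes[starts[:, None] + np.arange(read_length)]
    rate = error_profile(read_length) if error_profile is not None else error_rate
    err = rng.random(reads.shape) < rate
    shift = rng.integers(1, 4, size=reads.shape, dtype=np.uint8)
    reads = np.where(err, (reads + shift) % 4, reads)
    if random_strand:
        flip = rng.random(n) < 0.5
        reads[flip] = (3 - reads[flip])[:, ::-1]
    blob = _BASES[reads].tobytes().decode("ascii")
    return [blob[i * read_length : (i + 1) * read_length] for i in range(n)]


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    """Plain FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(seq: str, path: str | Path, name: str = "genome", width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def make_pair_fixture(
    cfg: SimConfig, out_dir: str | Path | None = None
) -> tuple[list[str], list[str], float]:
    """Two independent skims of a genome and its mutated copy.

    Returns ``(skim1, skim2, true_distance)`` as in-memory read lists; when
    ``out_dir`` is given the genomes (FASTA) and skims (FASTQ) are also
    written there.  Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = random_genome(cfg.genome_length, rng)
    mutant = mutate_genome(genome, cfg.distance, rng)
    skim1 = sample_reads(genome, cfg.coverage, cfg.read_length, cfg.error_rate, rng)
    skim2 = sample_reads(mutant, cfg.coverage, cfg.read_length, cfg.error_rate, rng)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome1.fa", "genome1")
        write_fasta(mutant, out / "genome2.fa", "genome2")
        write_fastq(skim1, out / "skim1.fq", "g1")
        write_fastq(skim2, out / "skim2.fq", "g2")
    return skim1, skim2, cfg.distance


def composed_distance(d1: float, d2: float) -> float:
    """Expected distance between two independent mutants of one ancestor.

    A site differs unless untouched in both copies or mutated to the same
    base (probability 1/3 given both mutated): d = d1 + d2 - (4/3) d1 d2.
    """
    return d1 + d2 - 4.0 / 3.0 * d1 * d2
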