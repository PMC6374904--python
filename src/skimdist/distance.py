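"""Jaccard-to-distance conversion, with and without coverage/error correction.

For two fully-covered, error-free genomes of equal length the Jaccard index
of their k-mer sets relates to the per-nucleotide substitution distance D by

    2J / (1 + J) = (1 - D)^k          =>   D = 1 - (2J / (J + 1))^(1/k)

(the exact inversion; Mash's published formula takes the further
approximation (1-D)^k ~ exp(-kD)).  A genome skim violates the
full-coverage assumption: k-mers are observed only with probability eta,
erroneous k-mers inflate the union, and the two skims may differ in genome
length.  With per-skim correction factors (eta_i, zeta_i) and estimated
genome lengths L_i from the profile module, the corrected estimate is

    D = 1 - ( 2 (zeta1 L1 + zeta2 L2) J
              / (eta1 eta2 (L1 + L2) (1 + J)) )^(1/k)

which reduces to the uncorrected form when eta = zeta = 1 and L1 = L2.
Out-of-model observations are clamped: a radicand above 1 (e.g. a skim
against itself) gives D = 0, and J = 0 or a non-positive radicand saturates
at D = 1; flags record either event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .profile import SkimProfile
from .sketch import Sketch, jaccard

DEFAULT_K = 31


@dataclass
class PairDistance:
    """One Jaccard estimate and its distance conversion, with clamp flags."""

    J: float
    D: float
    clamped_zero: bool = False   # radicand exceeded 1 -> D forced to 0
    saturated: bool = False      # J = 0 or radicand <= 0 -> D forced to 1
    d_jc: float | None = None    # Jukes-Cantor transform, on request


def jaccard_to_distance(J: float, k: int = DEFAULT_K) -> PairDistance:
    """Uncorrected conversion D = 1 - (2J/(J+1))^(1/k) (exact inversion)."""
    if not 0.0 <= J <= 1.0:
        raise ValueError("J must be in [0, 1]")
    if J == 0.0:
        return PairDistance(J=J, D=1.0, saturated=True)
    return PairDistance(J=J, D=1.0 - (2.0 * J / (J + 1.0)) ** (1.0 / k))


def mash_distance(J: float, k: int = DEFAULT_K) -> PairDistance:
    """Mash's log-approximate conversion D = (1/k) ln((J+1)/(2J))."""
    if not 0.0 <= J <= 1.0:
        raise ValueError("J must be in [0, 1]")
    if J == 0.0:
        return PairDistance(J=J, D=1.0, saturated=True)
    return PairDistance(J=J, D=math.log((J + 1.0) / (2.0 * J)) / k)


def skim_distance(J: float, p1: SkimProfile, p2: SkimProfile) -> PairDistance:
    """Coverage/error/length-corrected distance between two skims."""
    if p1.k != p2.k:
        raise ValueError(f"profile k mismatch: {p1.k} != {p2.k}")
    if not 0.0 <= J <= 1.0:
        raise ValueError("J must be in [0, 1]")
    k = p1.k
    if J == 0.0:
        return PairDistance(J=J, D=1.0, saturated=True)
    s_len = p1.zeta * p1.genome_length + p2.zeta * p2.genome_length
    denom = p1.eta * p2.eta * (p1.genome_length + p2.genome_length) * (1.0 + J)
    radicand = 2.0 * s_len * J / denom
    if radicand <= 0.0:
        return PairDistance(J=J, D=1.0, saturated=True)
    if radicand > 1.0:
        return PairDistance(J=J, D=0.0, clamped_zero=True)
    return PairDistance(J=J, D=1.0 - radicand ** (1.0 / k))


def forward_jaccard(D: float, p1: SkimProfile, p2: SkimProfile) -> float:
    """Model-expected Jaccard at distance D (exact inverse of skim_distance).

    Uses the same averaged-length numerator (L1+L2)/2 and length-weighted
    union zeta1 L1 + zeta2 L2 as the corrected estimator.
    """
    if p1.k != p2.k:
        raise ValueError("profile k mismatch")
    if not 0.0 <= D < 1.0:
        raise ValueError("D must be in [0, 1)")
    shared = (
        p1.eta * p2.eta
        * (p1.genome_length + p2.genome_length) / 2.0
        * (1.0 - D) ** p1.k
    )
    union = p1.zeta * p1.genome_length + p2.zeta * p2.genome_length - shared
    return shared / union


def jc_transform(D: float) -> float:
    """Jukes-Cantor substitutions-per-site: d = -(3/4) ln(1 - 4D/3)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if D >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * D / 3.0)


# ---------------------------------------------------------------------------
# all-pairs matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    names: list[str]
    values: np.ndarray                      # symmetric, zero diagonal
    pairs: dict[tuple[int, int], PairDistance] = field(default_factory=dict)

    def to_phylip(self, path: str | Path) -> None:
        """Square relaxed PHYLIP (names untruncated, full precision)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.names)}\n")
            for name, row in zip(self.names, self.values):
                fh.write(name + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")

    def to_tsv(self, path: str | Path, jc: bool = False) -> None:
        """Tidy TSV: name1 name2 J D d_jc flags, one row per unordered pair."""
        with open(path, "w") as fh:
            fh.write("name1\tname2\tJ\tD\td_jc\tflags\n")
            for (i, j), pd in sorted(self.pairs.items()):
                flags = ",".join(
                    f for f, on in
                    (("clamped_zero", pd.clamped_zero), ("saturated", pd.saturated))
                    if on
                ) or "-"
                d_jc = jc_transform(pd.D) if jc else (pd.d_jc if pd.d_jc is not None else "")
                fh.write(
                    f"{self.names[i]}\t{self.names[j]}\t{pd.J:.10g}\t{pd.D:.10g}"
                    f"\t{d_jc}\t{flags}\n"
                )


def pair_distance(
    entry1: tuple[Sketch, SkimProfile], entry2: tuple[Sketch, SkimProfile]
) -> PairDistance:
    """Corrected distance between two sketched skims."""
    sk1, prof1 = entry1
    sk2, prof2 = entry2
    return skim_distance(jaccard(sk1, sk2), prof1, prof2)


def all_pairs(
    entries: Sequence[tuple[str, Sketch, SkimProfile]], jc: bool = False
) -> DistanceMatrix:
    """Symmetric corrected-distance matrix over named skims."""
    if len(entries) < 2:
        raise ValueError("need at least 2 skims")
    names = [name for name, _, _ in entries]
    n = len(names)
    values = np.zeros((n, n))
    pairs: dict[tuple[int, int], PairDistance] = {}
    for i in range(n):
        for j in range(i + 1, n):
            try:
                pd = pair_distance(entries[i][1:], entries[j][1:])
            except ValueError as exc:
                raise ValueError(f"incompatible pair ({names[i]}, {names[j]}): {exc}") from exc
            if jc:
                pd.d_jc = jc_transform(pd.D)
            values[i, j] = values[j, i] = pd.D
            pairs[(i, j)] = pd
    return DistanceMatrix(names=names, values=values, pairs=pairs)
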