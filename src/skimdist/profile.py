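"""Co-estimation of sequencing coverage and base error from the k-mer spectrum.

A genome skim does not tell us its own coverage: large parts of the genome
are simply never sampled, so the zero-abundance bin of the k-mer spectrum is
unobservable.  The estimator works around this by modelling the number of
*error-free* reads covering a k-mer as Poisson with mean

    xi = lambda * rho,      rho = (1 - epsilon)^k,

where ``lambda = c (1 - k/l)`` is the k-mer coverage for base coverage ``c``
and read length ``l``, and ``epsilon`` is a constant per-base miscall rate.
For k large enough that every miscall creates a novel k-mer, the expected
spectrum is

    E[M_i] = M * xi^i / i! * exp(-xi)              for i >= 2
    E[M_1] = M * (xi * exp(-xi) + lambda - xi)     (erroneous k-mers pile
                                                    into the singleton bin)

Ratios of consecutive well-populated bins then give xi; the singleton excess
gives lambda; and epsilon follows from xi/lambda = rho.  The profile also
fixes the abundance filter m (drop k-mers seen < m times when coverage is
high enough that low-copy k-mers are almost surely erroneous) and the
Jaccard correction factors eta (probability a genomic k-mer is observed
error-free) and zeta (expected observed k-mers per genomic position,
erroneous ones included).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy import stats

from .kmers import KmerHistogram, ReadSet

#: base-coverage threshold above which low-abundance k-mers are filtered
COVERAGE_THRESHOLD = 5.0


@dataclass
class SkimProfile:
    """Estimated sequencing parameters of one skim, fixed before sketching."""

    k: int
    mean_read_length: float
    total_bases: int
    h: int = 0                # spectrum peak index used for estimation
    xi: float = 0.0           # error-free k-mer coverage
    lam: float = 0.0          # k-mer coverage
    epsilon: float = 0.0      # per-base error rate
    coverage: float = 0.0     # base coverage c
    genome_length: float = 0.0
    m: int = 1                # minimum multiplicity retained
    eta: float = 1.0
    zeta: float = 1.0
    regime: str = "low"       # low | high | assembly
    lambda_clamped: bool = False
    insufficient_signal: bool = False

    @property
    def rho(self) -> float:
        return (1.0 - self.epsilon) ** self.k

    # -- serialization (flat key=value, one per line) -----------------------

    def to_file(self, path: str | Path) -> None:
        fields = dict(
            k=self.k, mean_read_length=self.mean_read_length,
            total_bases=self.total_bases, h=self.h, xi=self.xi, lam=self.lam,
            epsilon=self.epsilon, coverage=self.coverage,
            genome_length=self.genome_length, m=self.m, eta=self.eta,
            zeta=self.zeta, regime=self.regime,
            lambda_clamped=int(self.lambda_clamped),
            insufficient_signal=int(self.insufficient_signal),
        )
        with open(path, "w") as fh:
            for key, val in fields.items():
                fh.write(f"{key}={val}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "SkimProfile":
        raw: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                if "=" in line:
                    key, val = line.rstrip("\n").split("=", 1)
                    raw[key] = val
        return cls(
            k=int(raw["k"]),
            mean_read_length=float(raw["mean_read_length"]),
            total_bases=int(raw["total_bases"]),
            h=int(raw["h"]), xi=float(raw["xi"]), lam=float(raw["lam"]),
            epsilon=float(raw["epsilon"]), coverage=float(raw["coverage"]),
            genome_length=float(raw["genome_length"]), m=int(raw["m"]),
            eta=float(raw["eta"]), zeta=float(raw["zeta"]),
            regime=raw["regime"],
            lambda_clamped=bool(int(raw.get("lambda_clamped", "0"))),
            insufficient_signal=bool(int(raw.get("insufficient_signal", "0"))),
        )


# ---------------------------------------------------------------------------
# estimation chain
# ---------------------------------------------------------------------------

def select_peak(hist: KmerHistogram) -> int:
    """Spectrum peak h = argmax_{i>=2} M_i (smallest index on ties).

    Bin 1 is excluded because erroneous k-mers inflate it; the estimator
    anchors on the best-populated multi-copy bin instead.
    """
    candidates = {i: m for i, m in hist.M.items() if i >= 2 and m > 0}
    if not candidates:
        raise ValueError(
            "histogram too sparse to estimate coverage/error "
            "(no k-mer seen more than once); supply epsilon/coverage overrides"
        )
    best = max(candidates.values())
    return min(i for i, m in candidates.items() if m == best)


def estimate_xi(hist: KmerHistogram, h: int) -> float:
    """Error-free k-mer coverage from the ratio of consecutive bins at the peak."""
    mh = hist.M.get(h, 0)
    if mh <= 0:
        raise ValueError(f"M_{h} is zero; cannot take bin ratio")
    return hist.M.get(h + 1, 0) / mh * (h + 1)


def estimate_lambda(hist: KmerHistogram, xi: float, h: int) -> tuple[float, bool]:
    """k-mer coverage from the singleton bin plus the error-free Poisson mass.

    Returns ``(lambda, clamped)``; lambda is clamped up to xi if the raw
    estimate is inconsistent (lambda < xi is impossible under the model).
    """
    if xi < 0:
        raise ValueError("xi must be >= 0")
    mh = hist.M.get(h, 0)
    if mh <= 0:
        raise ValueError(f"M_{h} is zero")
    m1 = hist.M.get(1, 0)
    lam = m1 / mh * xi**h / math.factorial(h) * math.exp(-xi) + xi * (1.0 - math.exp(-xi))
    if lam < xi:
        return xi, True
    return lam, False


def estimate_epsilon(xi: float, lam: float, k: int) -> float:
    """Per-base error rate from the error-free fraction xi/lambda = (1-eps)^k."""
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    if xi >= lam:
        if xi > lam:
            warnings.warn("xi > lambda (inconsistent histogram); epsilon set to 0")
        return 0.0
    eps = 1.0 - (xi / lam) ** (1.0 / k)
    return min(max(eps, 0.0), 0.5)


def base_coverage(lam: float, k: int, read_length: float) -> float:
    """Base coverage c from k-mer coverage: lambda = c (1 - k/l)."""
    if read_length <= k:
        raise ValueError("read length must exceed k")
    return lam / (1.0 - k / read_length)


def genome_length(total_bases: int, coverage: float) -> float:
    """Genome length as total sequence divided by coverage."""
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    return total_bases / coverage


def min_multiplicity(coverage: float) -> int:
    """Abundance filter: m = 1 below the coverage threshold, floor(c/5)+1 above."""
    if coverage < COVERAGE_THRESHOLD:
        return 1
    return int(coverage // COVERAGE_THRESHOLD) + 1


def correction_factors(lam: float, epsilon: float, k: int, m: int) -> tuple[float, float]:
    """Jaccard correction factors (eta, zeta) for a skim.

    Low-coverage regime (m = 1, erroneous k-mers kept):
        eta  = 1 - exp(-xi)               (k-mer observed error-free)
        zeta = eta + lambda (1 - rho)     (plus expected erroneous novels)
    High-coverage regime (m >= 2, low-copy k-mers filtered, errors removed):
        zeta = eta = P[Poisson(xi) >= m]
    with xi = lambda * (1 - epsilon)^k.
    """
    if lam < 0 or not 0 <= epsilon <= 0.5 or m < 1:
        raise ValueError("invalid arguments to correction_factors")
    rho = (1.0 - epsilon) ** k
    xi = lam * rho
    if m == 1:
        eta = 1.0 - math.exp(-xi)
        zeta = eta + lam * (1.0 - rho)
    else:
        eta = float(1.0 - stats.poisson.cdf(m - 1, xi)) if xi > 0 else 0.0
        zeta = eta
    return eta, zeta


def expected_histogram(
    M: float, lam: float, epsilon: float, k: int, i_max: int
) -> np.ndarray:
    """Model expectation E[M_i] for i = 1..i_max (index 0 of the result is i=1).

    M is the number of distinct k-mers in the underlying genome.
    """
    if lam <= 0 or not 0 <= epsilon <= 0.5:
        raise ValueError("need lambda > 0 and epsilon in [0, 0.5]")
    rho = (1.0 - epsilon) ** k
    xi = lam * rho
    i = np.arange(1, i_max + 1)
    exp_mi = M * stats.poisson.pmf(i, xi)
    exp_mi[0] = M * (xi * math.exp(-xi) + lam - xi)
    return exp_mi


def build_profile(
    hist: KmerHistogram | None,
    readstats: ReadSet,
    k: int,
    epsilon_override: float | None = None,
    coverage_override: float | None = None,
) -> SkimProfile:
    """Full estimation chain for one skim (or assembly).

    For assemblies every k-mer is assumed present exactly once and error-free:
    eta = zeta = 1, epsilon = 0, L = total sequence length.  For skims the
    chain is peak -> xi -> lambda -> epsilon -> c -> L -> m -> (eta, zeta);
    user overrides for epsilon and c replace the spectrum-based estimates
    (both must be given together when the spectrum is too sparse).
    """
    ell = readstats.mean_read_length
    prof = SkimProfile(k=k, mean_read_length=ell, total_bases=readstats.total_bases)
    if readstats.is_assembly:
        return replace(
            prof, regime="assembly", coverage=1.0, lam=1.0, xi=1.0,
            genome_length=float(readstats.total_bases), eta=1.0, zeta=1.0, m=1,
        )
    if ell <= k:
        raise ValueError("mean read length must exceed k")

    if epsilon_override is not None and coverage_override is not None:
        cov = float(coverage_override)
        eps = float(epsilon_override)
        lam = cov * (1.0 - k / ell)
        xi = lam * (1.0 - eps) ** k
        h, clamped, weak = 0, False, False
    else:
        if hist is None:
            raise ValueError("need a histogram or both epsilon and coverage overrides")
        h = select_peak(hist)
        xi = estimate_xi(hist, h)
        weak = xi == 0.0
        if weak:
            warnings.warn(
                f"insufficient signal: M_{h + 1} = 0; coverage estimate unreliable"
            )
        lam, clamped = estimate_lambda(hist, xi, h)
        eps = estimate_epsilon(xi, lam, k) if lam > 0 else 0.0
        if lam <= 0:
            raise ValueError("estimated lambda is zero; supply overrides")
        cov = base_coverage(lam, k, ell)

    L = genome_length(readstats.total_bases, cov)
    m = min_multiplicity(cov)
    eta, zeta = correction_factors(lam, eps, k, m)
    return replace(
        prof, h=h, xi=xi, lam=lam, epsilon=eps, coverage=cov, genome_length=L,
        m=m, eta=eta, zeta=zeta, regime="low" if m == 1 else "high",
        lambda_clamped=clamped, insufficient_signal=weak,
    )
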