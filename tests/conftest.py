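"""Shared fixtures: simulated genomes and skims reused across test modules.

Simulation-heavy fixtures are session-scoped so the expensive k-mer counting
runs once.  All seeds are fixed constants; every test is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import skimdist as sd

GENOME_LEN = 1_000_000
READ_LEN = 100
ERR = 0.01
K = 31


def run_pipeline(reads, k=K, s=10**7, hash_seed=42):
    """count -> histogram -> profile -> sketch for in-memory reads."""
    stats = sd.read_stats(reads)
    table = sd.count_kmers(reads, k)
    hist = sd.histogram(table)
    prof = sd.build_profile(hist, stats, k)
    sk = sd.build_sketch(table, s=s, m=prof.m, hash_seed=hash_seed)
    return table, hist, prof, sk


@pytest.fixture(scope="session")
def base_genome() -> str:
    return sd.random_genome(GENOME_LEN, seed=1701)


@pytest.fixture(scope="session")
def genome_kmer_count(base_genome) -> int:
    return sd.count_kmers([base_genome], K).n_distinct


@pytest.fixture(scope="session")
def recovery_skims(base_genome):
    """Skims of the base genome at c in {2, 4, 8}, eps=0.01, l=100."""
    out = {}
    rng = np.random.default_rng(2042)
    for c in (2, 4, 8):
        reads = sd.sample_reads(base_genome, c, READ_LEN, ERR, rng)
        table = sd.count_kmers(reads, K)
        hist = sd.histogram(table)
        prof = sd.build_profile(hist, sd.read_stats(reads), K)
        out[c] = (reads, table, hist, prof)
    return out


@pytest.fixture(scope="session")
def distance_sweep():
    """Skim pairs at true distance 0.05 and coverage 1/8x, 1x, 8x.

    Returns {coverage: (D_corrected, D_uncorrected, true_d)}.
    """
    out = {}
    for i, cov in enumerate((0.125, 1.0, 8.0)):
        cfg = sd.SimConfig(
            genome_length=GENOME_LEN, distance=0.05, coverage=cov,
            read_length=READ_LEN, error_rate=ERR, seed=3100 + i,
        )
        skim1, skim2, d = sd.make_pair_fixture(cfg)
        *_, p1, k1 = run_pipeline(skim1)
        *_, p2, k2 = run_pipeline(skim2)
        J = sd.jaccard(k1, k2)
        out[cov] = (sd.skim_distance(J, p1, p2).D, sd.jaccard_to_distance(J, K).D, d)
    return out


def make_profile(k=K, lam=2.0, epsilon=0.01, L=1e6, coverage=None, ell=100.0,
                 m=None) -> sd.SkimProfile:
    """Analytic profile with self-consistent correction factors (no data)."""
    cov = coverage if coverage is not None else lam / (1.0 - k / ell)
    m_eff = m if m is not None else sd.min_multiplicity(cov)
    eta, zeta = sd.correction_factors(lam, epsilon, k, m_eff)
    return sd.SkimProfile(
        k=k, mean_read_length=ell, total_bases=int(L * cov), xi=lam * (1 - epsilon) ** k,
        lam=lam, epsilon=epsilon, coverage=cov, genome_length=L, m=m_eff,
        eta=eta, zeta=zeta, regime="low" if m_eff == 1 else "high",
    )
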