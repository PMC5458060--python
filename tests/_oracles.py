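"""Independent brute-force oracles used by the unit and acceptance tests.

Everything here is written directly from first principles / the original
formula transcriptions, deliberately sharing no code with the package paths
it checks.
"""
from __future__ import annotations

import math

import numpy as np

MISSING = -1


def brute_force_window_pi(dosage: np.ndarray, pos: np.ndarray, start: int, size: int,
                          min_genotyped_mask: np.ndarray | None = None) -> float:
    """All-pairs allele-difference pi for one window, divided by window span.

    dosage: (sites, samples) with -1 missing.  Each diploid sample
    contributes two alleles; pairwise differences are counted over every
    unordered pair of observed alleles at each site.
    """
    total = 0.0
    for i in range(dosage.shape[0]):
        p = pos[i] - 1
        if not (start <= p < start + size):
            continue
        if min_genotyped_mask is not None and not min_genotyped_mask[i]:
            continue
        alleles = []
        for g in dosage[i]:
            if g == MISSING:
                continue
            alleles.extend([1] * int(g) + [0] * (2 - int(g)))
        n = len(alleles)
        if n < 2:
            continue
        diffs = sum(
            1 for a in range(n) for b in range(a + 1, n) if alleles[a] != alleles[b]
        )
        total += diffs / (n * (n - 1) / 2)
    return total / size


def wc84_components(d1: np.ndarray, d2: np.ndarray) -> tuple[float, float, float]:
    """Literal transcription of the Weir & Cockerham (1984) a, b, c for two
    diploid populations at one site (missing dosages excluded)."""
    stats = []
    for d in (d1, d2):
        d = np.asarray([g for g in d if g != MISSING], dtype=float)
        n = len(d)
        p = d.sum() / (2 * n)
        h = np.mean(d == 1)
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional HWE p-value by full enumeration with math.comb."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    probs = {}
    for het in range(n_rare % 2, n_rare + 1, 2):
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        # multinomial count of genotype configurations x 2^het phase factor
        probs[het] = (
            math.comb(n, het) * math.comb(n - het, hom_r) * 2 ** het
        )
    z = sum(probs.values())
    p_obs = probs[n_Aa] / z
    return min(1.0, sum(v / z for v in probs.values() if v / z <= p_obs * (1 + 1e-12)))


def dense_null_marginal(x: int, n: int, p0: float, omega: float, k: int = 100_000) -> float:
    """Brute-force censored-normal / binomial marginal on a dense midpoint grid."""
    from scipy.stats import binom, norm

    sigma = math.sqrt(omega * p0 * (1 - p0))
    edges = np.linspace(0.0, 1.0, k + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    cdf = norm.cdf((edges - p0) / sigma)
    cell = np.diff(cdf)
    lik = float(cell @ binom.pmf(x, n, mids))
    lik += cdf[0] * (x == 0) + (1 - cdf[-1]) * (x == n)
    return math.log(lik)
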