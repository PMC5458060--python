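"""Linkage disequilibrium from unphased genotypes: exact HWE test, EM r2, decay.

Two-locus r2 is computed from EM-estimated haplotype frequencies: for each
pair of sites the 3x3 genotype table is reduced to haplotype counts, the only
phase ambiguity being the double heterozygote, which the EM splits between
coupling (AB/ab) and repulsion (Ab/aB) according to the current frequency
estimates.  Sites entering the decay curve are pre-filtered on minor allele
frequency and on a conditional exact Hardy-Weinberg test (sites with
p < ``hwe_alpha`` dropped), mirroring the standard Haploview-style settings
(-maxdistance 1000 [kb] -minMAF 0.05 -hwcutoff 0.001).

The decay curve bins all within-chromosome pairs by physical distance and the
decay distance is where linear interpolation between bin means first crosses
the reference level (r2 = 0.2 by convention) from above.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .variants import MISSING, GenotypeMatrix, SampleTable

EM_MAX_ITER = 50
EM_TOL = 1e-8


@dataclass(frozen=True)
class LDConfig:
    """Pair selection and filtering parameters for the decay curve."""

    max_distance: int = 1_000_000  # bp, Haploview's -maxdistance is in kb
    min_maf: float = 0.05
    hwe_alpha: float = 0.001
    bin_width: int = 1_000

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not (0.0 < self.hwe_alpha < 1.0):
            raise ValueError("hwe_alpha must be in (0,1)")


@dataclass
class DecayCurve:
    """Mean r2 per physical-distance bin."""

    midpoints: np.ndarray  # bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_bp\tmean_r2\tn_pairs\n")
            for d, r, n in zip(self.midpoints, self.mean_r2, self.n_pairs):
                fh.write(f"{int(d)}\t{r:.6g}\t{int(n)}\n")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Conditional exact Hardy-Weinberg test (Wigginton-style, two-sided).

    Enumerates every heterozygote count compatible with the observed allele
    counts (same parity), computes each table's conditional probability and
    sums those no more probable than the observed table.  Monomorphic sites
    return 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    n_rare = min(n_A, n_a)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # P(het | n, n_rare) ∝ n! / (hom_r! het! hom_c!) * 2^het, normalised below
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = prob[hets == n_Aa]
    if obs.size == 0:  # parity mismatch cannot happen for valid counts
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    return float(min(1.0, prob[prob <= obs[0] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# EM haplotype frequencies and r2
# ---------------------------------------------------------------------------

def _pair_counts(gA: np.ndarray, gB: np.ndarray) -> np.ndarray:
    """9-vector of genotype-pair counts (gA in rows 0/1/2, gB in cols)."""
    ok = (gA != MISSING) & (gB != MISSING)
    counts = np.zeros(9)
    for a in range(3):
        for b in range(3):
            counts[3 * a + b] = np.sum(ok & (gA == a) & (gB == b))
    return counts


def _em_r2_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorised EM r2 for a (pairs x 9) genotype-pair count table.

    Haplotype classes are (ref,ref), (ref,alt), (alt,ref), (alt,alt).  Only
    the double-heterozygote cell (index 4) is phase-ambiguous.  Returns NaN
    for pairs where either site is monomorphic among the shared samples.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    n = counts.sum(axis=1)
    dh = counts[:, 4]
    # fixed haplotype contributions from unambiguous genotype pairs
    # genotype (a,b): contributes haplotypes per Mendelian decomposition
    base = np.zeros((counts.shape[0], 4))
    contrib = {
        (0, 0): ((0, 2),), (0, 1): ((0, 1), (1, 1)), (0, 2): ((1, 2),),
        (1, 0): ((0, 1), (2, 1)), (1, 2): ((1, 1), (3, 1)),
        (2, 0): ((2, 2),), (2, 1): ((2, 1), (3, 1)), (2, 2): ((3, 2),),
    }
    for (a, b), haps in contrib.items():
        cell = counts[:, 3 * a + b]
        for h, w in haps:
            base[:, h] += w * cell
    total = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (base + 0.5 * dh[:, None]) / np.maximum(total, 1)[:, None]
        for _ in range(EM_MAX_ITER):
            coup = f[:, 0] * f[:, 3]
            rep = f[:, 1] * f[:, 2]
            w = np.where(coup + rep > 0, coup / np.maximum(coup + rep, 1e-300), 0.5)
            newf = base.copy()
            newf[:, 0] += dh * w
            newf[:, 3] += dh * w
            newf[:, 1] += dh * (1 - w)
            newf[:, 2] += dh * (1 - w)
            newf /= np.maximum(total, 1)[:, None]
            delta = np.abs(newf - f).max()
            f = newf
            if delta < EM_TOL:
                break
        pA = f[:, 2] + f[:, 3]
        pB = f[:, 1] + f[:, 3]
        D = f[:, 3] - pA * pB
        denom = pA * (1 - pA) * pB * (1 - pB)
        r2 = np.where(denom > 0, D * D / np.maximum(denom, 1e-300), np.nan)
    r2 = np.where(n >= 2, r2, np.nan)
    return r2


def r2_pair(dosages_A: np.ndarray, dosages_B: np.ndarray) -> float:
    """EM-based r2 between two sites from unphased dosage vectors.

    Samples missing at either site are excluded pairwise; NaN when either
    site is monomorphic among the shared samples.
    """
    gA = np.asarray(dosages_A)
    gB = np.asarray(dosages_B)
    if gA.shape != gB.shape:
        raise ValueError("dosage vectors must be aligned")
    return float(_em_r2_from_counts(_pair_counts(gA, gB))[0])


def r2_matrix_banded(
    dosage: np.ndarray, pair_i: np.ndarray, pair_j: np.ndarray, chunk: int = 200_000
) -> np.ndarray:
    """EM r2 for an explicit list of site-index pairs over one dosage block."""
    S = dosage.shape[0]
    onehot = [np.asarray(dosage == a, dtype=np.float32) for a in range(3)]
    ok = np.asarray(dosage != MISSING, dtype=np.float32)
    out = np.empty(len(pair_i))
    for lo in range(0, len(pair_i), chunk):
        hi = min(lo + chunk, len(pair_i))
        ii, jj = pair_i[lo:hi], pair_j[lo:hi]
        counts = np.empty((hi - lo, 9))
        for a in range(3):
            Ia = onehot[a][ii]
            for b in range(3):
                counts[:, 3 * a + b] = np.einsum("ps,ps->p", Ia, onehot[b][jj])
        out[lo:hi] = _em_r2_from_counts(counts)
    return out


# ---------------------------------------------------------------------------
# Decay curve
# ---------------------------------------------------------------------------

def _usable_sites(dosage: np.ndarray, config: LDConfig) -> np.ndarray:
    ok = dosage != MISSING
    n = 2 * ok.sum(axis=1)
    alt = np.where(ok, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    maf = np.fmin(p, 1 - p)
    keep = maf > config.min_maf
    for i in np.flatnonzero(keep):
        d = dosage[i][ok[i]]
        pval = hwe_exact_p(int(np.sum(d == 0)), int(np.sum(d == 1)), int(np.sum(d == 2)))
        if pval < config.hwe_alpha:
            keep[i] = False
    return keep


def ld_decay(
    matrix: GenotypeMatrix,
    sample_table: SampleTable,
    population: str,
    config: LDConfig = LDConfig(),
) -> DecayCurve:
    """Mean r2 versus physical distance for one population.

    Sites failing the MAF or HWE filter are removed, all within-chromosome
    pairs separated by at most ``max_distance`` bp are EM-phased, and mean
    r2 is tabulated in ``bin_width`` distance bins.
    """
    members = [s for s in sample_table.members(population) if s in matrix.samples]
    sub = matrix.dosage[:, matrix.sample_indices(members)]
    keep = _usable_sites(sub, config)
    if keep.sum() < 2:
        raise ValueError("fewer than two usable sites after MAF/HWE filtering")

    n_bins = int(np.ceil(config.max_distance / config.bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for c in dict.fromkeys(str(x) for x in matrix.chrom):
        on = (matrix.chrom == c) & keep
        pos = matrix.pos[on]
        dos = sub[on]
        if len(pos) < 2:
            continue
        hi_bound = np.searchsorted(pos, pos + config.max_distance, side="right")
        pi_list, pj_list = [], []
        for i in range(len(pos)):
            js = np.arange(i + 1, hi_bound[i])
            pi_list.append(np.full(len(js), i))
            pj_list.append(js)
        pair_i = np.concatenate(pi_list).astype(np.intp)
        pair_j = np.concatenate(pj_list).astype(np.intp)
        if len(pair_i) == 0:
            continue
        r2 = r2_matrix_banded(dos, pair_i, pair_j)
        dist = (pos[pair_j] - pos[pair_i]).astype(np.int64)
        okp = ~np.isnan(r2)
        bins = np.minimum((dist[okp] - 1) // config.bin_width, n_bins - 1)
        np.add.at(sums, bins, r2[okp])
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    mids = (np.arange(n_bins) + 0.5) * config.bin_width
    present = counts > 0
    return DecayCurve(midpoints=mids[present], mean_r2=mean[present], n_pairs=counts[present])


def decay_distance(curve: DecayCurve, threshold: float = 0.2) -> float | None:
    """Distance where the decay curve first crosses ``threshold`` from above.

    Linear interpolation between adjacent bin means; None when the curve
    never exceeds the threshold or never drops below it.
    """
    d = np.asarray(curve.midpoints, dtype=float)
    v = np.asarray(curve.mean_r2, dtype=float)
    if len(d) == 0 or v[0] < threshold:
        return None
    for k in range(len(d)):
        if v[k] == threshold:
            return float(d[k])
        if k + 1 < len(d) and v[k] > threshold and v[k + 1] < threshold:
            frac = (v[k] - threshold) / (v[k] - v[k + 1])
            return float(d[k] + frac * (d[k + 1] - d[k]))
    return None
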