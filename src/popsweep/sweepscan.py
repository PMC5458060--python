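"""Cross-population composite-likelihood sweep scan (XP-CLR style).

The scan contrasts two models of allele-frequency change in an *objective*
population (here: cultivated) relative to a *reference* population (wild
progenitor), at SNPs with reference frequency p0 and objective allele counts
x out of n:

* Null (drift): the latent objective frequency q follows a normal law
  centred at p0 with variance  omega * p0 * (1 - p0), truncated to (0,1)
  with the two tail masses placed as point masses at 0 and 1 (fixation /
  loss by drift).  The observation is Binomial(n, q), marginalised
  numerically over the latent grid.
* Sweep: a fraction c of lineages escapes the sweep by recombination and
  keeps the pre-sweep frequency; the rest hitchhike with the favoured
  mutation's background allele.  Given pre-sweep frequency q (drawn from
  the drift law), the post-sweep frequency is  1 - c*(1 - q)  with
  probability q (the favoured mutation arose on the background of the
  tracked allele) and  c*q  otherwise.  At c=1 this reduces exactly to the
  null.  The escape probability grows with genetic distance d from the
  selected site:  c = 1 - exp(-d * ln(2*Ne*s) / s),  clipped to [0,1];
  when 2*Ne*s <= 1 there is no effective sweep and c = 1.

At each grid point the composite log-likelihood ratio is maximised over a
grid of selection coefficients, combining SNPs inside a genetic-distance
window.  SNPs that are strongly correlated in the reference population
(r2 > ``corr_threshold``) are down-weighted by 1/m, m being the number of
correlated SNPs in the window, so that redundant linked SNPs do not inflate
the composite score.  Scores are tabulated as maxima in non-overlapping
10-kb windows; candidate sweep regions are the top 3% of windows merged by
adjacency, kept if their best window reaches the top-1% level, and finally
cross-filtered against the top half of the pi_wild/pi_cult ratio windows.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import gammaln, ndtr

from .linkage import r2_matrix_banded
from .popstats import Region, WindowSpec, WindowTrack, merge_regions, quantile_mask
from .variants import MISSING, GenotypeMatrix, SampleTable

logger = logging.getLogger("popsweep")

OMEGA_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Physical-to-genetic anchors (bp -> cM) per chromosome, piecewise linear."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (bp, cM) sorted by bp

    def __post_init__(self) -> None:
        for c, (bp, cm) in self.anchors.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"anchors on {c} must have increasing bp")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"genetic positions on {c} must be non-decreasing")
            self.anchors[c] = (bp, cm)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        data: dict[str, list[tuple[float, float]]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                c, bp, cm = line.split()[:3]
                data.setdefault(c, []).append((float(bp), float(cm)))
        anchors = {}
        for c, rows in data.items():
            arr = np.asarray(sorted(rows), dtype=float)
            anchors[c] = (arr[:, 0], arr[:, 1])
        return cls(anchors)


def interpolate_genetic_position(
    bp, chrom: str | None = None, genetic_map: GeneticMap | None = None,
    fallback_cM_per_Mb: float = 1.0,
) -> np.ndarray | float:
    """Genetic position in Morgans for physical position(s) bp.

    Piecewise-linear between anchors; beyond the terminal anchors (or with no
    map at all) extrapolation uses ``fallback_cM_per_Mb``.
    """
    arr = np.asarray(bp, dtype=float)
    rate_m_per_bp = fallback_cM_per_Mb / 100.0 / 1e6
    if genetic_map is None or chrom not in genetic_map.anchors:
        out = arr * rate_m_per_bp
        return float(out) if np.isscalar(bp) else out
    abp, acm = genetic_map.anchors[chrom]
    out = np.interp(arr, abp, acm) / 100.0
    below = arr < abp[0]
    above = arr > abp[-1]
    out = np.where(below, acm[0] / 100.0 - (abp[0] - arr) * rate_m_per_bp, out)
    out = np.where(above, acm[-1] / 100.0 + (arr - abp[-1]) * rate_m_per_bp, out)
    return float(out) if np.isscalar(bp) else out


# ---------------------------------------------------------------------------
# Model parameters
# ---------------------------------------------------------------------------

@dataclass
class SweepModel:
    """Drift and selection parameters of the composite-likelihood scan."""

    omega: float | None = None  # estimated from genome-wide SNPs when None
    s_grid: np.ndarray = field(default_factory=lambda: np.logspace(np.log10(1e-4), np.log10(0.5), 15))
    Ne: float = 10_000.0
    corr_threshold: float = 0.7
    window_morgans: float = 0.0005
    max_snps_per_window: int = 100
    grid_bp: int = 100
    n_latent: int = 512

    def __post_init__(self) -> None:
        if self.omega is not None and self.omega <= 0:
            raise ValueError("omega must be positive")
        if np.any(np.asarray(self.s_grid) <= 0):
            raise ValueError("selection coefficients must be positive")
        if not (0 < self.corr_threshold <= 1):
            raise ValueError("corr_threshold must be in (0,1]")


@dataclass
class CLRTrack:
    """Composite-likelihood-ratio scores on the bp grid of one scan."""

    chrom: np.ndarray
    bp: np.ndarray
    clr: np.ndarray  # NaN where no SNPs fell in the window
    s_hat: np.ndarray
    n_snps: np.ndarray

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for c, b, v in zip(self.chrom, self.bp, self.clr):
                if not math.isnan(v):
                    fh.write(f"{c}\t{int(b)}\t{int(b) + 1}\t{v:.6g}\n")


# ---------------------------------------------------------------------------
# Drift variance
# ---------------------------------------------------------------------------

def estimate_drift_variance(p_ref: np.ndarray, counts_obj: np.ndarray, n_obj: np.ndarray) -> float:
    """Method-of-moments drift variance omega from genome-wide SNPs.

    omega = mean over SNPs of [(p_obj_hat - p_ref)^2 - p_obj_hat(1-p_obj_hat)/n_obj]
    / [p_ref (1 - p_ref)]; the subtraction removes binomial sampling noise
    from the observed objective frequencies.  Requires >= 500 SNPs
    polymorphic in the reference; clipped below at 1e-6.
    """
    p_ref = np.asarray(p_ref, dtype=float)
    x = np.asarray(counts_obj, dtype=float)
    n = np.asarray(n_obj, dtype=float)
    ok = (p_ref > 0) & (p_ref < 1) & (n > 0)
    if ok.sum() < 500:
        raise ValueError("need >= 500 reference-polymorphic SNPs to estimate omega")
    p_hat = x[ok] / n[ok]
    num = (p_hat - p_ref[ok]) ** 2 - p_hat * (1 - p_hat) / n[ok]
    ratio = num / (p_ref[ok] * (1 - p_ref[ok]))
    return float(max(OMEGA_FLOOR, ratio.mean()))


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

#: escape-probability grid on which the scan tabulates per-SNP likelihood
#: ratios; log-dense near both c=0 (strong hitchhiking, steep pmf) and c=1
#: (model approaches the null)
_C_GRID = np.unique(np.concatenate([
    [0.0, 1.0],
    np.logspace(-4.0, np.log10(0.5), 40),
    1.0 - np.logspace(-7.0, np.log10(0.5), 36),
]))


def _binom_pmf(x: int, n: int, p: np.ndarray) -> np.ndarray:
    """Binomial pmf vectorised over success probabilities, exact at p=0/1."""
    p = np.asarray(p, dtype=float)
    logc = gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = logc
        if x > 0:
            lp = lp + x * np.log(np.maximum(p, 1e-320))
        if n - x > 0:
            lp = lp + (n - x) * np.log(np.maximum(1.0 - p, 1e-320))
    out = np.exp(lp)
    out = np.where(p <= 0.0, 1.0 * (x == 0), out)
    out = np.where(p >= 1.0, 1.0 * (x == n), out)
    return out


def _latent_cells(p0: float, omega: float, n_latent: int):
    """Censored-normal drift law as a discrete latent distribution.

    The interval (0,1) is split into ``n_latent`` cells; each cell carries
    its exact truncated-normal mass at its conditional-mean representative
    point, and the two tail masses sit at 0 and 1.  Returns (q, mass).
    """
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0,1)")
    if omega <= 0:
        raise ValueError("omega must be positive")
    sigma = math.sqrt(omega * p0 * (1.0 - p0))
    edges = np.linspace(0.0, 1.0, n_latent + 1)
    z = (edges - p0) / sigma
    cdf = ndtr(z)
    pdf = np.exp(-0.5 * z * z) / math.sqrt(2.0 * math.pi)
    cell = np.diff(cdf)
    mids = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        qc = p0 - sigma * np.diff(pdf) / cell
    qc = np.where((cell > 1e-300) & np.isfinite(qc), qc, mids)
    qc = np.clip(qc, edges[:-1], edges[1:])
    q = np.concatenate([[0.0], qc, [1.0]])
    mass = np.concatenate([[cdf[0]], cell, [1.0 - cdf[-1]]])
    return q, mass


def null_loglik(x, n, p0, omega: float, n_latent: int = 512) -> float:
    """Log marginal likelihood of x alt alleles out of n under drift alone."""
    if not (0 <= x <= n):
        raise ValueError("x must be in [0, n]")
    q, mass = _latent_cells(float(p0), omega, n_latent)
    lik = float(mass @ _binom_pmf(int(x), int(n), q))
    return math.log(max(lik, 1e-300))


def escape_probability(d_morgans, s, Ne: float) -> np.ndarray | float:
    """Probability a lineage recombines off the sweeping haplotype.

    c = 1 - exp(-d * ln(2*Ne*s) / s), clipped to [0,1]; with 2*Ne*s <= 1
    there is no effective sweep and c = 1 everywhere.
    """
    d = np.asarray(d_morgans, dtype=float)
    s_arr = np.asarray(s, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    with np.errstate(over="ignore"):
        c = 1.0 - np.exp(-d * np.log(np.maximum(2.0 * Ne * s_arr, 1.0 + 1e-12)) / s_arr)
    c = np.clip(c, 0.0, 1.0)
    c = np.where(2.0 * Ne * s_arr <= 1.0, 1.0, c)
    if np.isscalar(d_morgans) and np.isscalar(s):
        return float(c)
    return c


def sweep_loglik(x, n, p0, omega: float, c: float, n_latent: int = 512) -> float:
    """Log marginal likelihood under the hitchhiking model with escape prob c.

    The pre-sweep frequency q follows the drift law around p0; after the
    sweep a lineage keeps its allele with probability c (escape), otherwise
    it carries the favoured background, so the post-sweep frequency is
    1 - c*(1-q) with probability q and c*q with probability 1-q.  c=1
    recovers the null exactly.
    """
    if not (0.0 <= c <= 1.0):
        raise ValueError("c must be in [0,1]")
    if not (0 <= x <= n):
        raise ValueError("x must be in [0, n]")
    q, mass = _latent_cells(float(p0), omega, n_latent)
    p_hit = 1.0 - c * (1.0 - q)
    p_miss = c * q
    lik = float(
        (mass * (q * _binom_pmf(int(x), int(n), p_hit)
                 + (1.0 - q) * _binom_pmf(int(x), int(n), p_miss))).sum()
    )
    return math.log(max(lik, 1e-300))


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

@dataclass
class _SnpData:
    """Per-chromosome precomputed SNP quantities for the scan."""

    bp: np.ndarray
    gpos: np.ndarray  # Morgans
    log_null: np.ndarray
    lr_table: np.ndarray  # (n_snps, len(_C_GRID)) sweep-vs-null log-ratio
    corr_neighbors: list[np.ndarray]  # sorted indices with ref-pop r2 > threshold


def _snp_likelihood_tables(p0, x, n, omega: float, n_latent: int):
    """Per-SNP null log-likelihood and sweep/null log-ratio on _C_GRID.

    The latent drift law is discretised on a shared midpoint grid (cell
    masses from CDF differences); SNPs sharing (x, n) reuse one kernel so
    the tabulation is a handful of matrix products.
    """
    S = len(p0)
    edges = np.linspace(0.0, 1.0, n_latent + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    qg = np.concatenate([[0.0], mids, [1.0]])  # (Q,)
    sigma = np.sqrt(omega * p0 * (1.0 - p0))
    cdf = ndtr((edges[None, :] - p0[:, None]) / sigma[:, None])
    mass = np.concatenate([cdf[:, :1], np.diff(cdf, axis=1), 1.0 - cdf[:, -1:]], axis=1)

    cg = _C_GRID
    p_hit = 1.0 - cg[:, None] * (1.0 - qg[None, :])  # (C, Q)
    p_miss = cg[:, None] * qg[None, :]
    null_lik = np.empty(S)
    lr = np.empty((S, len(cg)))
    combos, inverse = np.unique(np.stack([x, n], axis=1), axis=0, return_inverse=True)
    for ci, (xc, nc) in enumerate(combos):
        members = np.flatnonzero(inverse == ci)
        pmf_q = _binom_pmf(int(xc), int(nc), qg)
        null_lik[members] = mass[members] @ pmf_q
        kernel = (qg[None, :] * _binom_pmf(int(xc), int(nc), p_hit)
                  + (1.0 - qg[None, :]) * _binom_pmf(int(xc), int(nc), p_miss))  # (C, Q)
        sweep_lik = mass[members] @ kernel.T  # (G, C)
        lr[members] = (np.log(np.maximum(sweep_lik, 1e-300))
                       - np.log(np.maximum(null_lik[members], 1e-300))[:, None])
    return np.log(np.maximum(null_lik, 1e-300)), lr


def _prepare_snps(
    bp: np.ndarray, gpos: np.ndarray, p0: np.ndarray, x: np.ndarray, n: np.ndarray,
    ref_dosage: np.ndarray, model: SweepModel, omega: float,
) -> _SnpData:
    log_null, lr_table = _snp_likelihood_tables(
        np.asarray(p0, float), np.asarray(x), np.asarray(n), omega, model.n_latent
    )

    # reference-population correlation neighbours within one window span
    S = len(bp)
    neighbors: list[list[int]] = [[] for _ in range(S)]
    pi_list, pj_list = [], []
    hi = np.searchsorted(gpos, gpos + model.window_morgans, side="right")
    for i in range(S):
        js = np.arange(i + 1, hi[i])
        pi_list.append(np.full(len(js), i))
        pj_list.append(js)
    if S and sum(len(v) for v in pj_list):
        pair_i = np.concatenate(pi_list).astype(np.intp)
        pair_j = np.concatenate(pj_list).astype(np.intp)
        r2 = r2_matrix_banded(ref_dosage, pair_i, pair_j)
        linked = r2 > model.corr_threshold
        for i, j in zip(pair_i[linked], pair_j[linked]):
            neighbors[i].append(j)
            neighbors[j].append(i)
    return _SnpData(
        bp=bp, gpos=gpos, log_null=log_null, lr_table=lr_table,
        corr_neighbors=[np.asarray(sorted(v), dtype=np.intp) for v in neighbors],
    )


def _interp_lr(lr_rows: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Linear interpolation of per-SNP log-ratios over _C_GRID.

    lr_rows: (w, C) table slice; c: (..., w) escape probabilities.
    """
    idx = np.clip(np.searchsorted(_C_GRID, c), 1, len(_C_GRID) - 1)
    c0 = _C_GRID[idx - 1]
    c1 = _C_GRID[idx]
    t = (c - c0) / (c1 - c0)
    rows = np.broadcast_to(np.arange(lr_rows.shape[0]), c.shape)
    return lr_rows[rows, idx - 1] * (1.0 - t) + lr_rows[rows, idx] * t


def _weights(snps: _SnpData, lo: int, hi: int) -> np.ndarray:
    """1/m down-weighting inside the kept SNP range [lo, hi)."""
    m = np.ones(hi - lo)
    for k, i in enumerate(range(lo, hi)):
        nb = snps.corr_neighbors[i]
        if len(nb):
            m[k] += np.searchsorted(nb, hi, side="left") - np.searchsorted(nb, lo, side="left")
    return 1.0 / m


def clr_at_gridpoint(
    grid_bp_position: float, snps: _SnpData, model: SweepModel, omega: float,
    grid_gpos: float | None = None,
) -> tuple[float, float, int]:
    """CLR and argmax selection coefficient at one grid point.

    Collects SNPs within +/- window_morgans/2 of the grid point (nearest
    ``max_snps_per_window`` kept), down-weights correlated SNPs by 1/m and
    maximises the weighted composite log-likelihood ratio over the s grid.
    """
    g = grid_gpos if grid_gpos is not None else interpolate_genetic_position(grid_bp_position)
    half = model.window_morgans / 2.0
    lo = int(np.searchsorted(snps.gpos, g - half, side="left"))
    hi = int(np.searchsorted(snps.gpos, g + half, side="right"))
    lo, hi = _truncate_nearest(snps.gpos, lo, hi, g, model.max_snps_per_window)
    if hi <= lo:
        return float("nan"), float("nan"), 0
    w = _weights(snps, lo, hi)
    d = np.abs(snps.gpos[lo:hi] - g)
    c = escape_probability(d[None, :], np.asarray(model.s_grid)[:, None], model.Ne)
    ll = _interp_lr(snps.lr_table[lo:hi], c)
    scores = 2.0 * (ll * w[None, :]).sum(axis=1)
    k = int(np.argmax(scores))
    if scores[k] <= 0.0:  # the nested no-sweep model (c = 1) wins
        return 0.0, float("nan"), hi - lo
    return float(scores[k]), float(model.s_grid[k]), hi - lo


def _truncate_nearest(gpos: np.ndarray, lo: int, hi: int, g: float, max_snps: int) -> tuple[int, int]:
    while hi - lo > max_snps:
        if g - gpos[lo] >= gpos[hi - 1] - g:
            lo += 1
        else:
            hi -= 1
    return lo, hi


def scan_chromosome(
    chrom: str, bp: np.ndarray, gpos: np.ndarray, p0: np.ndarray, x: np.ndarray,
    n: np.ndarray, ref_dosage: np.ndarray, model: SweepModel, omega: float,
    chrom_len: int, genetic_map: GeneticMap | None = None,
    fallback_cM_per_Mb: float = 1.0,
) -> CLRTrack:
    """CLR scores on a regular bp grid along one chromosome."""
    snps = _prepare_snps(bp, gpos, p0, x, n, ref_dosage, model, omega)
    grid = np.arange(0, chrom_len, model.grid_bp, dtype=np.int64)
    grid_g = np.asarray(interpolate_genetic_position(
        grid.astype(float), chrom, genetic_map, fallback_cM_per_Mb))
    clr = np.full(len(grid), np.nan)
    s_hat = np.full(len(grid), np.nan)
    n_used = np.zeros(len(grid), dtype=np.int64)
    half = model.window_morgans / 2.0
    los = np.searchsorted(gpos, grid_g - half, side="left")
    his = np.searchsorted(gpos, grid_g + half, side="right")
    s_col = np.asarray(model.s_grid)[:, None]
    log_s = np.log(np.maximum(2.0 * model.Ne * s_col, 1.0 + 1e-12)) / s_col
    no_sweep = (2.0 * model.Ne * s_col <= 1.0).ravel()  # c = 1: model reduces to null
    prev = (-1, -1)
    w = None
    for k in range(len(grid)):
        lo, hi = _truncate_nearest(gpos, int(los[k]), int(his[k]), grid_g[k], model.max_snps_per_window)
        if hi <= lo:
            continue
        if (lo, hi) != prev:
            w = _weights(snps, lo, hi)
            prev = (lo, hi)
        d = np.abs(gpos[lo:hi] - grid_g[k])
        with np.errstate(over="ignore"):
            c = 1.0 - np.exp(-d[None, :] * log_s)
        np.clip(c, 0.0, 1.0, out=c)
        if no_sweep.any():
            c[no_sweep, :] = 1.0
        ll = _interp_lr(snps.lr_table[lo:hi], c)
        scores = 2.0 * (ll @ w)
        j = int(np.argmax(scores))
        if scores[j] <= 0.0:  # nested no-sweep model (c = 1) wins
            clr[k] = 0.0
            s_hat[k] = np.nan
        else:
            clr[k] = scores[j]
            s_hat[k] = model.s_grid[j]
        n_used[k] = hi - lo
    return CLRTrack(
        chrom=np.full(len(grid), chrom, dtype=object), bp=grid,
        clr=clr, s_hat=s_hat, n_snps=n_used,
    )


def scan_genome(
    matrix: GenotypeMatrix,
    sample_table: SampleTable,
    reference: str,
    objective: str,
    model: SweepModel = None,
    genetic_map: GeneticMap | None = None,
    chrom_lengths: dict[str, int] | None = None,
    fallback_cM_per_Mb: float = 1.0,
) -> tuple[CLRTrack, float]:
    """Run the scan genome-wide; returns the CLR track and the omega used.

    Sites monomorphic in the reference (or with <2 genotyped samples in
    either population) are dropped: the drift null needs 0 < p0 < 1.
    """
    model = model or SweepModel()
    ref_members = [s for s in sample_table.members(reference) if s in matrix.samples]
    obj_members = [s for s in sample_table.members(objective) if s in matrix.samples]
    ref_d = matrix.dosage[:, matrix.sample_indices(ref_members)]
    obj_d = matrix.dosage[:, matrix.sample_indices(obj_members)]

    ref_ok = ref_d != MISSING
    obj_ok = obj_d != MISSING
    n_ref = 2 * ref_ok.sum(axis=1)
    n_obj = 2 * obj_ok.sum(axis=1)
    p0 = np.where(n_ref > 0, np.where(ref_ok, ref_d, 0).sum(axis=1) / np.maximum(n_ref, 1), np.nan)
    x = np.where(obj_ok, obj_d, 0).sum(axis=1)
    usable = (n_ref >= 4) & (n_obj >= 4) & (p0 > 0) & (p0 < 1)
    logger.info("sweep scan: %d/%d SNPs usable", int(usable.sum()), matrix.n_sites)

    omega = model.omega
    if omega is None:
        omega = estimate_drift_variance(p0[usable], x[usable], n_obj[usable])
        logger.info("sweep scan: omega estimated at %.4f", omega)

    tracks: list[CLRTrack] = []
    for c in dict.fromkeys(str(ch) for ch in matrix.chrom):
        on = (matrix.chrom == c) & usable
        length = (chrom_lengths or {}).get(c, int(matrix.pos[matrix.chrom == c].max()))
        gpos = interpolate_genetic_position(
            matrix.pos[on].astype(float), c, genetic_map, fallback_cM_per_Mb
        )
        tracks.append(scan_chromosome(
            c, matrix.pos[on], np.asarray(gpos), p0[on], x[on], n_obj[on],
            ref_d[on], model, omega, length, genetic_map, fallback_cM_per_Mb,
        ))
    return CLRTrack(
        chrom=np.concatenate([t.chrom for t in tracks]),
        bp=np.concatenate([t.bp for t in tracks]),
        clr=np.concatenate([t.clr for t in tracks]),
        s_hat=np.concatenate([t.s_hat for t in tracks]),
        n_snps=np.concatenate([t.n_snps for t in tracks]),
    ), float(omega)


# ---------------------------------------------------------------------------
# Tabulation and region calling
# ---------------------------------------------------------------------------

def tabulate_windows(track: CLRTrack, window: int = 10_000,
                     chrom_lengths: dict[str, int] | None = None) -> WindowTrack:
    """Maximum CLR per non-overlapping ``window``-bp window (NaN if empty)."""
    spec = WindowSpec(size=window, step=window)
    chroms, starts_all, vals, ns = [], [], [], []
    for c in dict.fromkeys(str(ch) for ch in track.chrom):
        on = track.chrom == c
        bp = track.bp[on]
        clr = track.clr[on]
        length = (chrom_lengths or {}).get(c, int(bp.max()) + 1 if len(bp) else window)
        starts = np.arange(0, max(length, 1), window, dtype=np.int64)
        v = np.full(len(starts), np.nan)
        cnt = np.zeros(len(starts), dtype=np.int64)
        ok = ~np.isnan(clr)
        idx = (bp[ok] // window).astype(np.intp)
        in_range = idx < len(starts)
        idx = idx[in_range]
        vals_ok = clr[ok][in_range]
        v[np.unique(idx)] = -np.inf
        np.maximum.at(v, idx, vals_ok)
        np.add.at(cnt, idx, 1)
        v[cnt == 0] = np.nan
        chroms.append(np.full(len(starts), c, dtype=object))
        starts_all.append(starts)
        vals.append(v)
        ns.append(cnt)
    return WindowTrack(
        chrom=np.concatenate(chroms), start=np.concatenate(starts_all),
        value=np.concatenate(vals), n_sites=np.concatenate(ns), spec=spec,
    )


def call_sweeps(
    clr_windows: WindowTrack,
    pi_ratio_track: WindowTrack | None,
    top_group: float = 0.03,
    top_region: float = 0.01,
    pi_top: float = 0.50,
) -> list[Region]:
    """Candidate sweep regions from tabulated CLR windows.

    1. threshold windows at the top ``top_group`` of defined CLR values;
    2. merge adjacent passing windows into regions (score = max window);
    3. keep regions whose score reaches the top ``top_region`` window level;
    4. drop regions not overlapping any window in the top ``pi_top`` of the
       pi-ratio track (>= 1 bp overlap).
    """
    defined = clr_windows.defined
    if not defined.any():
        raise ValueError("no defined CLR windows")
    vals = clr_windows.value[defined]
    thr_group, strict_g = quantile_mask(vals, top_group)
    passing = defined & (clr_windows.value > thr_group if strict_g
                         else clr_windows.value >= thr_group)
    regions = merge_regions([
        Region(str(c), int(s), int(s) + clr_windows.spec.size, float(v))
        for c, s, v in zip(
            clr_windows.chrom[passing], clr_windows.start[passing], clr_windows.value[passing]
        )
    ])
    thr_region, strict_r = quantile_mask(vals, top_region)
    regions = [r for r in regions
               if (r.score > thr_region if strict_r else r.score >= thr_region)]

    if pi_ratio_track is not None and pi_top < 1.0:
        pdef = pi_ratio_track.defined
        if not pdef.any():
            raise ValueError("pi-ratio track has no defined windows")
        thr_pi, strict_p = quantile_mask(pi_ratio_track.value[pdef], pi_top)
        qual = pdef & (pi_ratio_track.value > thr_pi if strict_p
                       else pi_ratio_track.value >= thr_pi)
        qc = pi_ratio_track.chrom[qual]
        qs = pi_ratio_track.start[qual].astype(int)
        qe = qs + pi_ratio_track.spec.size
        kept = []
        for r in regions:
            on = qc == r.chrom
            if np.any((qs[on] < r.end) & (r.start < qe[on])):
                kept.append(r)
        dropped = len(regions) - len(kept)
        if dropped:
            logger.info("call_sweeps: %d region(s) excluded by the pi-ratio filter", dropped)
        regions = kept
    return sorted(regions, key=lambda r: (r.chrom, r.start))
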