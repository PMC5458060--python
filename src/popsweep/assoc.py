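"""Stratification-corrected association for a quantitative trait.

Genotypes are normalised the EIGENSTRAT way: missing values imputed to the
site mean, columns centred and scaled by sqrt(p(1-p)) with p the mean alt
dosage / 2.  The top k principal axes of the sample covariance capture
population structure; both genotype and phenotype are residualised on those
axes and the adjusted statistic is (n - k - 1) * rho^2, rho being the
correlation of the two residual vectors, referred to a chi-square with one
degree of freedom.  This is the quantitative-trait analogue of the
Armitage-trend correction used for stratified association scans.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .variants import MISSING, GenotypeMatrix

logger = logging.getLogger("popsweep")

DEFAULT_K = 10
DEFAULT_ALPHA = 1e-4


@dataclass
class PCAResult:
    """Top-k axes of genetic variation across samples."""

    axes: np.ndarray  # (n_samples, k), orthonormal columns
    eigenvalues: np.ndarray  # length k, non-increasing
    k: int


@dataclass
class AssocResult:
    """Per-SNP adjusted association statistics."""

    chrom: np.ndarray
    pos: np.ndarray
    stat: np.ndarray
    p: np.ndarray
    effect_sign: np.ndarray
    significant: np.ndarray
    alpha: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "pos": self.pos, "stat": self.stat,
            "p": self.p, "effect_sign": self.effect_sign, "significant": self.significant,
        })

    def to_tsv(self, path) -> None:
        df = self.to_dataframe()
        df["stat"] = df["stat"].map(lambda v: f"{v:.6g}")
        df["p"] = df["p"].map(lambda v: f"{v:.6g}")
        df.to_csv(path, sep="\t", index=False)


def normalize_genotypes(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """EIGENSTRAT normalisation of the dosage matrix.

    Returns (normalised sites x samples matrix, boolean mask of retained
    polymorphic sites).  Missing entries are imputed to the site mean before
    centring; columns are scaled by sqrt(p(1-p)).
    """
    d = matrix.dosage.astype(float)
    ok = matrix.dosage != MISSING
    n_ok = ok.sum(axis=1)
    keep = n_ok > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ok, d, 0).sum(axis=1) / np.maximum(n_ok, 1)
    d = np.where(ok, d, mean[:, None])
    p = mean / 2.0
    poly = keep & (p > 0) & (p < 1)
    if (~poly).sum():
        logger.info("normalize_genotypes: dropped %d monomorphic/all-missing sites", int((~poly).sum()))
    d = d[poly] - mean[poly, None]
    d /= np.sqrt(p[poly] * (1 - p[poly]))[:, None]
    return d, poly


def compute_pca(normalized: np.ndarray, k: int = DEFAULT_K) -> PCAResult:
    """Top-k eigenvectors of the sample-by-sample covariance of the
    normalised genotype matrix; deterministic up to the fixed sign rule
    (largest-magnitude coordinate positive)."""
    n = normalized.shape[1]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    cov = (normalized.T @ normalized) / normalized.shape[0]
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1][:k]
    w = w[order]
    v = v[:, order]
    for j in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    return PCAResult(axes=v, eigenvalues=w, k=k)


def _design_basis(axes: np.ndarray, n: int) -> np.ndarray:
    """Orthonormal basis of span(intercept, axes); projection is then exact OLS."""
    design = np.column_stack([np.ones(n), axes]) if axes.shape[1] else np.ones((n, 1))
    q, _ = np.linalg.qr(design)
    return q


def _residualize(y: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """OLS residual of y on intercept + axes (idempotent projection)."""
    q = _design_basis(axes, len(y))
    return y - q @ (q.T @ y)


def eigenstrat_adjusted_stat(
    genotype: np.ndarray, phenotype: np.ndarray, pca: PCAResult | None
) -> tuple[float, float]:
    """Adjusted association statistic and p-value for one SNP.

    Both vectors are residualised on the PCA axes (none when pca is None or
    k=0); statistic = (n - k - 1) * rho^2 ~ chi2(1) under the null.
    """
    g = np.asarray(genotype, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    axes = pca.axes if pca is not None else np.zeros((len(g), 0))
    k = axes.shape[1]
    rg = _residualize(g, axes)
    ry = _residualize(y, axes)
    vg = float(rg @ rg)
    vy = float(ry @ ry)
    if vg <= 1e-10 * len(g) or vy <= 0.0:
        return 0.0, 1.0
    rho = float(rg @ ry) / np.sqrt(vg * vy)
    stat = (len(g) - k - 1) * rho ** 2
    return float(stat), float(chi2.sf(stat, df=1))


def gwas_scan(
    matrix: GenotypeMatrix,
    phenotype: pd.Series | dict[str, float],
    k: int = DEFAULT_K,
    alpha: float = DEFAULT_ALPHA,
) -> AssocResult:
    """Stratification-adjusted scan of every SNP against a quantitative trait.

    ``phenotype`` maps sample id to trait value (e.g. bolting days); only
    phenotyped samples enter the scan.  Missing genotypes are mean-imputed
    via the normalisation step.  No multiple-testing correction is applied:
    significance is the fixed threshold p < ``alpha``.
    """
    pheno = pd.Series(phenotype, dtype=float)
    samples = [s for s in matrix.samples if s in pheno.index and np.isfinite(pheno[s])]
    if len(samples) < 20:
        logger.warning("gwas_scan: only %d phenotyped samples; scan is underpowered", len(samples))
    sub = matrix.take_samples(samples)
    y = pheno[samples].to_numpy()
    norm, poly = normalize_genotypes(sub)
    pca = compute_pca(norm, k=k) if k > 0 else None
    axes = pca.axes if pca is not None else np.zeros((len(samples), 0))

    # vectorised residual correlations over all SNPs at once
    q = _design_basis(axes, len(samples))
    ry = y - q @ (q.T @ y)
    rg = norm - (norm @ q) @ q.T
    vy = float(ry @ ry)
    vg = np.einsum("ij,ij->i", rg, rg)
    num = rg @ ry
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(vg > 0, num / np.sqrt(np.maximum(vg, 1e-300) * vy), 0.0)
    n = len(samples)
    stat = (n - axes.shape[1] - 1) * rho ** 2
    p = chi2.sf(stat, df=1)
    p = np.where(vg > 0, p, 1.0)

    full_stat = np.zeros(matrix.n_sites)
    full_p = np.ones(matrix.n_sites)
    full_sign = np.zeros(matrix.n_sites, dtype=np.int8)
    full_stat[poly] = stat
    full_p[poly] = p
    full_sign[poly] = np.sign(num).astype(np.int8)
    return AssocResult(
        chrom=matrix.chrom, pos=matrix.pos, stat=full_stat, p=full_p,
        effect_sign=full_sign, significant=full_p < alpha, alpha=alpha,
    )


def read_phenotype_tsv(path) -> pd.Series:
    """Two-column (sample, value) phenotype table, header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if not np.issubdtype(np.asarray(pd.to_numeric(df.iloc[0, 1:2], errors="coerce")).dtype, np.number) \
            or pd.isna(pd.to_numeric(df.iloc[0, 1], errors="coerce")):
        df = df.iloc[1:]
    return pd.Series(pd.to_numeric(df.iloc[:, 1]).to_numpy(), index=df.iloc[:, 0].astype(str).to_numpy())


def plot_manhattan(result: AssocResult, path) -> None:
    """Manhattan plot with the significance threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    for i, c in enumerate(dict.fromkeys(str(x) for x in result.chrom)):
        on = result.chrom == c
        ax.scatter(result.pos[on] + offset, -np.log10(np.maximum(result.p[on], 1e-300)),
                   s=4, color=f"C{i % 2}")
        offset += int(result.pos[on].max())
    ax.axhline(-np.log10(result.alpha), color="k", ls="--", lw=0.8)
    ax.set_xlabel("genome position (bp, concatenated)")
    ax.set_ylabel(r"$-\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_qq(result: AssocResult, path) -> None:
    """QQ plot of observed versus expected -log10 p-values."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = -np.log10(np.sort(np.maximum(result.p, 1e-300)))
    exp = -np.log10((np.arange(1, len(obs) + 1) - 0.5) / len(obs))[::-1]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(np.sort(exp), np.sort(obs)[::1], ".", ms=3)
    lim = max(exp.max(), obs.max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.set_xlabel("expected $-\\log_{10} P$")
    ax.set_ylabel("observed $-\\log_{10} P$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
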