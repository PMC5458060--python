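"""Nucleotide diversity, Weir-Cockerham FST, sliding windows and region calling.

Per-site nucleotide diversity is the mean pairwise allele difference
pi = c1*(n-c1)/C(n,2) over the n non-missing alleles at a site.  Windowed pi
divides the window's summed site values by the window span in bp, so
monomorphic (non-SNP) positions contribute zero, matching the convention for
diversity scans over a fixed genomic grid.  Differentiation uses the
Weir & Cockerham (1984) variance components a (between populations),
b (between individuals within populations) and c (within individuals);
window FST is the ratio of sums  sum(a) / sum(a+b+c).

Windows sit on a per-chromosome grid anchored at 0 (default 10 kb windows,
1 kb step).  Outlier calling takes the empirical top-``fraction`` of defined
window values -- threshold at the ascending order statistic of rank
ceil((1-fraction)*m), ties included -- and merges passing windows that
overlap or abut into regions scored by their best window.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .variants import MISSING, GenotypeMatrix, SampleTable

DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 1_000


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window grid: ``size`` bp windows every ``step`` bp, anchored at 0."""

    size: int = DEFAULT_WINDOW
    step: int = DEFAULT_STEP

    def __post_init__(self) -> None:
        if not (self.size >= self.step > 0):
            raise ValueError("require size >= step > 0")


@dataclass
class WindowTrack:
    """Per-window statistic values on a regular grid; NaN marks undefined windows."""

    chrom: np.ndarray
    start: np.ndarray  # 0-based window start
    value: np.ndarray
    n_sites: np.ndarray
    spec: WindowSpec

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.value)

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.spec == other.spec
            and len(self.start) == len(other.start)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
        )

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for c, s, v in zip(self.chrom, self.start, self.value):
                if not math.isnan(v):
                    fh.write(f"{c}\t{s}\t{s + self.spec.size}\t{v:.6g}\n")


@dataclass
class Region:
    """Merged genomic interval (0-based half-open) with an outlier score."""

    chrom: str
    start: int
    end: int
    score: float
    n_windows: int = 1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("region end must exceed start")

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


def write_regions_bed(regions: Sequence[Region], path) -> None:
    """Regions as BED6 (name=region index, score column = region score)."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tregion_{i + 1}\t{r.score:.6g}\t.\n")


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(dosages: np.ndarray) -> float:
    """Mean pairwise difference at one site from a population's dosage vector.

    With c1 alt alleles among n non-missing alleles: pi = c1*(n-c1)/C(n,2).
    Undefined (NaN) when fewer than 2 alleles are genotyped.
    """
    d = np.asarray(dosages)
    ok = d != MISSING
    n = 2 * int(ok.sum())
    if n < 2:
        return float("nan")
    c1 = int(d[ok].sum())
    return c1 * (n - c1) / (n * (n - 1) / 2)


def _site_pi_vector(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised site_pi over a (sites x samples) dosage block.

    Returns (pi, genotyped_fraction); pi is NaN where <2 alleles observed.
    """
    ok = dosage != MISSING
    n = 2 * ok.sum(axis=1)
    c1 = np.where(ok, dosage, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, c1 * (n - c1) / np.maximum(n * (n - 1) / 2, 1), np.nan)
    return pi, ok.mean(axis=1)


def _window_starts(chrom_len: int, spec: WindowSpec) -> np.ndarray:
    return np.arange(0, max(chrom_len, 1), spec.step, dtype=np.int64)


def _windowed_sum(
    pos: np.ndarray, values: np.ndarray, chrom_len: int, spec: WindowSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum ``values`` of sites (1-based pos) into sliding windows.

    Returns (starts, sums, counts).  A site at 1-based pos p lies in window
    [w, w+size) iff w <= p-1 < w+size.
    """
    starts = _window_starts(chrom_len, spec)
    cum = np.concatenate([[0.0], np.cumsum(values)])
    cnt = np.concatenate([[0], np.arange(1, len(pos) + 1)])
    p0 = pos - 1  # 0-based site coordinates
    left = np.searchsorted(p0, starts, side="left")
    right = np.searchsorted(p0, starts + spec.size, side="left")
    return starts, cum[right] - cum[left], (cnt[right] - cnt[left]).astype(np.int64)


def _chrom_order(matrix: GenotypeMatrix) -> list[str]:
    return list(dict.fromkeys(str(c) for c in matrix.chrom))


def windowed_pi(
    matrix: GenotypeMatrix,
    sample_table: SampleTable,
    population: str,
    spec: WindowSpec = WindowSpec(),
    min_genotyped: float = 0.90,
    chrom_lengths: dict[str, int] | None = None,
) -> WindowTrack:
    """Sliding-window per-bp nucleotide diversity for one population.

    Sites genotyped in fewer than ``min_genotyped`` of the whole accession
    panel (all samples in the matrix, so that every population is scored on
    one common site set) are excluded; window value = sum of site pi /
    window size.
    """
    members = [s for s in sample_table.members(population) if s in matrix.samples]
    if len(members) < 2:
        raise ValueError(f"population {population!r} needs >=2 samples")
    sub = matrix.dosage[:, matrix.sample_indices(members)]
    pi, _ = _site_pi_vector(sub)
    panel_frac = (matrix.dosage != MISSING).mean(axis=1)
    usable = (panel_frac >= min_genotyped) & ~np.isnan(pi)
    pi = np.where(usable, pi, 0.0)

    chroms, starts_all, vals, ns = [], [], [], []
    for c in _chrom_order(matrix):
        on = matrix.chrom == c
        length = (chrom_lengths or {}).get(c, int(matrix.pos[on].max()))
        starts, sums, counts = _windowed_sum(matrix.pos[on], pi[on], length, spec)
        counts_used, _ = _count_in_windows(matrix.pos[on][usable[on]], length, spec)
        chroms.append(np.full(len(starts), c, dtype=object))
        starts_all.append(starts)
        vals.append(sums / spec.size)
        ns.append(counts_used)
    return WindowTrack(
        chrom=np.concatenate(chroms), start=np.concatenate(starts_all),
        value=np.concatenate(vals), n_sites=np.concatenate(ns), spec=spec,
    )


def _count_in_windows(pos: np.ndarray, chrom_len: int, spec: WindowSpec):
    starts = _window_starts(chrom_len, spec)
    p0 = pos - 1
    left = np.searchsorted(p0, starts, side="left")
    right = np.searchsorted(p0, starts + spec.size, side="left")
    return (right - left).astype(np.int64), starts


def mean_pi(track: WindowTrack) -> float:
    """Genome-wide mean of defined window values (per-bp)."""
    return float(np.nanmean(track.value))


def pi_ratio(track_wild: WindowTrack, track_cult: WindowTrack) -> WindowTrack:
    """Per-window pi_wild / pi_cult; windows with pi_cult == 0 are undefined."""
    if not track_wild.same_grid(track_cult):
        raise ValueError("pi tracks are not on the same window grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(track_cult.value > 0, track_wild.value / track_cult.value, np.nan)
    return WindowTrack(
        chrom=track_wild.chrom, start=track_wild.start, value=ratio,
        n_sites=np.minimum(track_wild.n_sites, track_cult.n_sites), spec=track_wild.spec,
    )


# ---------------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------------

def _wc_components_vector(d1: np.ndarray, d2: np.ndarray):
    """Weir-Cockerham (1984) a, b, c per site for two diploid populations.

    d1, d2: (sites x samples) dosage blocks.  Sites where either population
    has <2 genotyped samples are NaN in all three components.
    """
    comps = []
    stats = []
    for d in (d1, d2):
        ok = d != MISSING
        n = ok.sum(axis=1).astype(float)  # genotyped individuals
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(ok, d, 0).sum(axis=1) / np.maximum(2 * n, 1)
            h = np.where(ok, d == 1, False).sum(axis=1) / np.maximum(n, 1)
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def fst_site_components(dosages_pop1: np.ndarray, dosages_pop2: np.ndarray) -> tuple[float, float, float]:
    """Weir-Cockerham variance components (a, b, c) at a single site."""
    a, b, c = _wc_components_vector(
        np.asarray(dosages_pop1, dtype=np.int8)[None, :],
        np.asarray(dosages_pop2, dtype=np.int8)[None, :],
    )
    return float(a[0]), float(b[0]), float(c[0])


def windowed_fst(
    matrix: GenotypeMatrix,
    sample_table: SampleTable,
    populations: tuple[str, str],
    spec: WindowSpec = WindowSpec(),
    chrom_lengths: dict[str, int] | None = None,
) -> WindowTrack:
    """Ratio-of-sums Weir-Cockerham FST per sliding window.

    Window value = sum(a) / sum(a+b+c) over the window's usable sites;
    windows with zero (or undefined) denominator are NaN.
    """
    m1 = [s for s in sample_table.members(populations[0]) if s in matrix.samples]
    m2 = [s for s in sample_table.members(populations[1]) if s in matrix.samples]
    if len(m1) < 2 or len(m2) < 2:
        raise ValueError("both populations need >=2 samples")
    a, b, c = _wc_components_vector(
        matrix.dosage[:, matrix.sample_indices(m1)],
        matrix.dosage[:, matrix.sample_indices(m2)],
    )
    usable = ~np.isnan(a)
    num = np.where(usable, a, 0.0)
    den = np.where(usable, a + b + c, 0.0)

    chroms, starts_all, vals, ns = [], [], [], []
    for ch in _chrom_order(matrix):
        on = matrix.chrom == ch
        length = (chrom_lengths or {}).get(ch, int(matrix.pos[on].max()))
        starts, num_sum, _ = _windowed_sum(matrix.pos[on], num[on], length, spec)
        _, den_sum, _ = _windowed_sum(matrix.pos[on], den[on], length, spec)
        counts, _ = _count_in_windows(matrix.pos[on][usable[on]], length, spec)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(den_sum > 0, num_sum / np.where(den_sum > 0, den_sum, 1.0), np.nan)
        chroms.append(np.full(len(starts), ch, dtype=object))
        starts_all.append(starts)
        vals.append(v)
        ns.append(counts)
    return WindowTrack(
        chrom=np.concatenate(chroms), start=np.concatenate(starts_all),
        value=np.concatenate(vals), n_sites=np.concatenate(ns), spec=spec,
    )


def mean_fst(matrix, sample_table, populations, **kw) -> float:
    """Genome-wide ratio-of-sums FST over all usable sites (single 'window')."""
    m1 = [s for s in sample_table.members(populations[0]) if s in matrix.samples]
    m2 = [s for s in sample_table.members(populations[1]) if s in matrix.samples]
    a, b, c = _wc_components_vector(
        matrix.dosage[:, matrix.sample_indices(m1)],
        matrix.dosage[:, matrix.sample_indices(m2)],
    )
    ok = ~np.isnan(a)
    return float(a[ok].sum() / (a[ok] + b[ok] + c[ok]).sum())


# ---------------------------------------------------------------------------
# Quantile thresholding and region merging
# ---------------------------------------------------------------------------

def quantile_threshold(values: np.ndarray, top_fraction: float) -> float:
    """Ascending order statistic at rank ceil((1-f)*m); ties pass above-or-equal."""
    v = np.sort(np.asarray(values, dtype=float))
    m = len(v)
    if m == 0:
        raise ValueError("no defined values to threshold")
    k = math.ceil((1.0 - top_fraction) * m)
    if k <= 0:
        return -math.inf
    if k > m:
        return math.inf
    return float(v[k - 1])


def quantile_mask(values: np.ndarray, top_fraction: float) -> tuple[float, bool]:
    """Threshold and tie policy for a top-``top_fraction`` cut.

    Ties at the threshold are included (above-or-equal) unless doing so
    inflates the passing fraction beyond twice the requested one — the
    degenerate-spike guard: a large probability mass exactly at the
    threshold (e.g. a constant track, or a score floored at zero) switches
    the cut to strictly-greater.  Returns (threshold, strict).
    """
    v = np.asarray(values, dtype=float)
    thr = quantile_threshold(v, top_fraction)
    if not np.isfinite(thr):
        return thr, False
    strict = (v >= thr).mean() > 2.0 * top_fraction
    return thr, strict


def merge_regions(regions: Sequence[Region]) -> list[Region]:
    """Merge overlapping or abutting regions; score = max, n_windows summed."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    out: list[Region] = []
    for r in ordered:
        if out and out[-1].chrom == r.chrom and r.start <= out[-1].end:
            last = out[-1]
            out[-1] = Region(
                last.chrom, last.start, max(last.end, r.end),
                max(last.score, r.score), last.n_windows + r.n_windows,
            )
        else:
            out.append(Region(r.chrom, r.start, r.end, r.score, r.n_windows))
    return out


def top_quantile_regions(
    track: WindowTrack, top_fraction: float, merge: bool = True
) -> list[Region]:
    """Call outlier regions from the top ``top_fraction`` of defined windows.

    Windows with value >= the empirical threshold are converted to intervals
    and (optionally) merged when they overlap or abut; each region's score is
    the maximum member-window value.
    """
    defined = track.defined
    m = int(defined.sum())
    if m == 0:
        raise ValueError("track has no defined windows")
    if top_fraction <= 0:
        return []
    if m < 1.0 / top_fraction:
        raise ValueError("too few defined windows for the requested quantile")
    thr, strict = quantile_mask(track.value[defined], top_fraction)
    passing = defined & (track.value > thr if strict else track.value >= thr)
    regions = [
        Region(str(c), int(s), int(s) + track.spec.size, float(v))
        for c, s, v in zip(track.chrom[passing], track.start[passing], track.value[passing])
    ]
    return merge_regions(regions) if merge else sorted(regions, key=lambda r: (r.chrom, r.start))


def genes_in_regions(regions: Sequence[Region], gff_path) -> list[list[str]]:
    """Gene IDs whose span overlaps each region by >= 1 bp."""
    import gffutils

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique"
    )
    genes = [(g.seqid, g.start - 1, g.end, g.id) for g in db.features_of_type("gene")]
    out = []
    for r in regions:
        out.append([gid for (c, s, e, gid) in genes if c == r.chrom and s < r.end and r.start < e])
    return out
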