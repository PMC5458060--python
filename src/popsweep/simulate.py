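"""Two-population synthetic data with planted domestication sweeps.

The generator emulates the statistical structure of a transcriptome-derived
SNP study of a crop and its wild progenitor:

* **Allele frequencies** follow a hierarchical Balding-Nichols model: an
  ancestral frequency p_anc ~ Uniform(0.05, 0.95) per site, and each
  population drifts to p_P ~ Beta(p_anc(1-F)/F, (1-p_anc)(1-F)/F), so that
  Var(p_P | p_anc) = F * p_anc * (1 - p_anc).  F_cult >= F_wild encodes a
  (weak) domestication bottleneck.
* **Haplotypes** are drawn with a Markov copying scheme: each haplotype
  carries a latent uniform that is reused from the previous site with
  probability exp(-delta_bp / ld_block_scale) and redrawn otherwise; the
  allele is the latent quantile against the site frequency.  Marginals stay
  Bernoulli(p_site) exactly while r2 decays roughly as exp(-d/scale).
* **Sweeps** act at the haplotype level in the cultivated population: inside
  each sweep interval a haplotype is "swept" with probability ``intensity``
  and then carries the alt allele at every interior site (the hitchhiking
  background); escapes keep their neutral alleles.
* **Read evidence**: per genotype, depth ~ Poisson(mean_depth), alt reads ~
  Binomial(depth, dosage/2), and a fraction ``missing_rate`` of entries is
  masked to depth 0.  VCF genotypes are then re-called from those depths
  with the >=3-read / >25% allele-fraction rule.
* **Phenotype**: bolting days for the cultivated accessions,
  y = baseline + effect_size * dosage(causal SNP) + Normal(0, residual_sd).

SNPs are restricted to genic intervals (transcriptome ascertainment); the
genome FASTA is generated with stop-free codons inside gene models so that
codon-degeneracy annotation runs cleanly on the simulated output.

All randomness flows from the single integer seed in :class:`SimConfig`
through one numpy Generator; identical configs give byte-identical files.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .popstats import Region
from .variants import (CULTIVATED, MISSING, WILD, GenotypeMatrix, SampleTable,
                       call_genotype_from_depths, write_vcf)

BASELINE_DAYS = 50.0  # intercept of the bolting phenotype
_GENE_LEN = 3_000
_GENE_SPACING = 5_000

# the 61 sense codons of the standard code, used to build stop-free CDS
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: cultivated haplotypes fix the alt allele inside
    [start, end) with probability ``intensity`` each."""

    chrom: str
    start: int
    end: int
    intensity: float = 0.9

    def __post_init__(self) -> None:
        if self.end - self.start < 10_000:
            raise ValueError("sweep interval must span at least one 10-kb window")
        if not (0 < self.intensity <= 1):
            raise ValueError("intensity must be in (0, 1]")


def _default_chroms() -> dict[str, int]:
    return {"chr1": 5_000_000, "chr2": 5_000_000}


def _default_sweeps() -> tuple[SweepSpec, ...]:
    return (
        SweepSpec("chr1", 1_000_000, 1_050_000, 0.9),
        SweepSpec("chr1", 3_200_000, 3_250_000, 0.9),
        SweepSpec("chr2", 2_000_000, 2_050_000, 0.9),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study design of the synthetic two-population experiment.

    Defaults mirror a desk-scale version of a domestication study: a small
    wild-progenitor panel against a larger cultivated panel, a weak
    bottleneck (F_cult > F_wild), LD decaying within a few kb and three
    planted 50-kb sweeps.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    genic_intervals: tuple[tuple[str, int, int], ...] | None = None  # None: regular gene grid
    n_sites: int = 20_000
    n_wild: int = 8
    n_cult: int = 30
    F_wild: float = 0.05
    F_cult: float = 0.10
    p_anc_range: tuple[float, float] = (0.05, 0.95)  # ancestral-frequency support
    sweeps: tuple[SweepSpec, ...] = field(default_factory=_default_sweeps)
    ld_block_scale: float = 2_000.0
    mean_depth: float = 20.0
    missing_rate: float = 0.05
    causal_site_index: int | None = None  # None: auto-pick (see simulate_phenotype)
    effect_size: float = 5.0  # days per alt allele
    residual_sd: float = 2.0  # days
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wild < 2 or self.n_cult < 2:
            raise ValueError("need at least two samples per population")
        if not (0 <= self.F_wild < 1 and 0 <= self.F_cult < 1):
            raise ValueError("drift parameters F must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        for sw in self.sweeps:
            if sw.chrom not in self.chrom_lengths or sw.end > self.chrom_lengths[sw.chrom]:
                raise ValueError(f"sweep {sw} outside the genome")

    @property
    def genome_length(self) -> int:
        return sum(self.chrom_lengths.values())

    def genes(self) -> list[tuple[str, int, int]]:
        """Genic intervals (0-based half-open); a regular grid by default."""
        if self.genic_intervals is not None:
            return list(self.genic_intervals)
        out = []
        for c, L in self.chrom_lengths.items():
            for s in range(1_000, L - _GENE_LEN, _GENE_SPACING):
                out.append((c, s, s + _GENE_LEN))
        return out

    @property
    def wild_samples(self) -> list[str]:
        return [f"wild_{i + 1:02d}" for i in range(self.n_wild)]

    @property
    def cult_samples(self) -> list[str]:
        return [f"cult_{i + 1:02d}" for i in range(self.n_cult)]

    def sample_table(self) -> SampleTable:
        pops = {s: WILD for s in self.wild_samples}
        pops.update({s: CULTIVATED for s in self.cult_samples})
        return SampleTable(pops)


@dataclass
class SimTruth:
    """Everything the tests need to score recovery."""

    sweep_regions: list[Region]
    p_anc: np.ndarray
    p_wild: np.ndarray
    p_cult: np.ndarray
    causal_site_index: int | None
    hap_wild: np.ndarray  # (2*n_wild, n_sites)
    hap_cult: np.ndarray


@dataclass
class Simulation:
    """A complete realised dataset."""

    config: SimConfig
    truth: SimTruth
    matrix: GenotypeMatrix  # depth-called genotypes with AD
    true_dosage: np.ndarray
    phenotype: dict[str, float]
    genome: dict[str, np.ndarray]  # chrom -> byte array of bases

    @property
    def sample_table(self) -> SampleTable:
        return self.config.sample_table()


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def simulate_frequencies(config: SimConfig, rng: np.random.Generator):
    """Balding-Nichols frequencies: (p_anc, p_wild, p_cult) per site."""
    p_anc = rng.uniform(*config.p_anc_range, size=config.n_sites)
    out = []
    for F in (config.F_wild, config.F_cult):
        if F >= 1:
            raise ValueError("F must be < 1")
        if F == 0:
            out.append(p_anc.copy())
        else:
            a = p_anc * (1 - F) / F
            b = (1 - p_anc) * (1 - F) / F
            out.append(rng.beta(a, b))
    return p_anc, out[0], out[1]


def _site_positions(config: SimConfig, rng: np.random.Generator):
    """Distinct SNP positions inside genic intervals, sorted by (chrom, pos).

    Returns (chrom array, 1-based pos array)."""
    genes = config.genes()
    spans = np.array([e - s for (_, s, e) in genes], dtype=float)
    total = spans.sum()
    if config.n_sites > total:
        raise ValueError("more SNPs requested than genic bp available")
    offsets = np.concatenate([[0.0], np.cumsum(spans)])
    # sample distinct offsets in the concatenated genic coordinate system
    flat = rng.choice(int(total), size=config.n_sites, replace=False)
    flat.sort()
    gene_idx = np.searchsorted(offsets, flat, side="right") - 1
    chroms = np.asarray([genes[i][0] for i in gene_idx], dtype=object)
    pos0 = np.asarray([genes[i][1] for i in gene_idx]) + (flat - offsets[gene_idx]).astype(np.int64)
    order = np.lexsort((pos0, np.asarray([str(c) for c in chroms])))
    return chroms[order], (pos0[order] + 1).astype(np.int64)


def simulate_haplotypes(freqs: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                        n_haplotypes: int, ld_block_scale: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Markov-copying haplotypes with per-site marginal Bernoulli(freqs).

    Each haplotype keeps a latent uniform; with probability
    exp(-delta_bp/scale) the previous site's latent is reused (copying the
    allele association), otherwise a fresh uniform is drawn.
    """
    S = len(pos)
    hap = np.empty((n_haplotypes, S), dtype=np.int8)
    u = rng.uniform(size=n_haplotypes)
    prev_chrom = None
    prev_pos = 0
    fresh = rng.uniform(size=(n_haplotypes, S))
    copy_draw = rng.uniform(size=(n_haplotypes, S))
    for j in range(S):
        if chrom[j] != prev_chrom:
            p_copy = 0.0
        elif ld_block_scale <= 0:
            p_copy = 0.0
        else:
            p_copy = float(np.exp(-(pos[j] - prev_pos) / ld_block_scale))
        keep = copy_draw[:, j] < p_copy
        u = np.where(keep, u, fresh[:, j])
        hap[:, j] = u < freqs[j]
        prev_chrom, prev_pos = chrom[j], pos[j]
    return hap


def apply_sweeps(hap_cult: np.ndarray, chrom: np.ndarray, pos: np.ndarray,
                 config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Fix the alt allele on swept cultivated haplotypes inside each sweep."""
    out = hap_cult.copy()
    for sw in config.sweeps:
        inside = (chrom == sw.chrom) & (pos - 1 >= sw.start) & (pos - 1 < sw.end)
        swept = rng.uniform(size=out.shape[0]) < sw.intensity
        out[np.ix_(swept, np.flatnonzero(inside))] = 1
    return out


def simulate_reads_and_genotypes(dosage: np.ndarray, config: SimConfig,
                                 rng: np.random.Generator):
    """Poisson depths and binomial allele splits per genotype.

    Returns (ad_ref, ad_alt); masked (missing) entries have depth 0.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    depth = rng.poisson(config.mean_depth, size=dosage.shape)
    if config.missing_rate > 0:
        depth[rng.uniform(size=dosage.shape) < config.missing_rate] = 0
    alt = rng.binomial(depth, dosage / 2.0)
    return (depth - alt).astype(np.int32), alt.astype(np.int32)


def pick_causal_site(chrom, pos, dosage_cult, config: SimConfig) -> int | None:
    """Deterministic causal-SNP choice: the first site with cultivated
    MAF >= 0.2 lying outside every sweep interval."""
    ok = dosage_cult != MISSING
    n = 2 * ok.sum(axis=1)
    p = np.where(ok, dosage_cult, 0).sum(axis=1) / np.maximum(n, 1)
    maf = np.minimum(p, 1 - p)
    in_sweep = np.zeros(len(pos), dtype=bool)
    for sw in config.sweeps:
        in_sweep |= (chrom == sw.chrom) & (pos - 1 >= sw.start) & (pos - 1 < sw.end)
    cand = np.flatnonzero((maf >= 0.2) & ~in_sweep & (n >= 4))
    return int(cand[0]) if len(cand) else None


def simulate_phenotype(dosage_cult: np.ndarray, causal_index: int | None,
                       config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Bolting days for the cultivated panel from the causal SNP dosage."""
    n = dosage_cult.shape[1]
    noise = rng.normal(0.0, config.residual_sd, size=n) if config.residual_sd > 0 else np.zeros(n)
    if causal_index is None or config.effect_size == 0:
        return BASELINE_DAYS + noise
    d = dosage_cult[causal_index].astype(float)
    if np.all(d == d[0]):
        warnings.warn("causal site is monomorphic in the cultivated panel; effect unidentifiable")
    d = np.where(d == MISSING, np.nanmean(np.where(d == MISSING, np.nan, d)), d)
    return BASELINE_DAYS + config.effect_size * d + noise


def _simulate_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Random genome with stop-free codon structure inside genic intervals."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = {
        c: rng.choice(bases, size=L).copy()
        for c, L in config.chrom_lengths.items()
    }
    codons = np.asarray([list(c) for c in _SENSE_CODONS], dtype="S1")
    strands = {}
    for gi, (c, s, e) in enumerate(config.genes()):
        n_codon = (e - s) // 3
        seq = codons[rng.integers(0, len(codons), size=n_codon)].reshape(-1)
        seq[:3] = np.frombuffer(b"ATG", dtype="S1")
        strand = "+" if gi % 2 == 0 else "-"
        strands[(c, s, e)] = strand
        if strand == "-":
            lut = np.zeros(256, dtype="S1")
            for a, b in zip(b"ACGT", b"TGCA"):
                lut[a] = bytes([b])
            seq = lut[seq.view(np.uint8)][::-1]
        genome[c][s:s + 3 * n_codon] = seq
    return genome


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(config: SimConfig) -> Simulation:
    """Run every stage under a single seeded generator."""
    rng = np.random.default_rng(config.seed)
    p_anc, p_wild, p_cult = simulate_frequencies(config, rng)
    chrom, pos = _site_positions(config, rng)
    hap_wild = simulate_haplotypes(p_wild, chrom, pos, 2 * config.n_wild,
                                   config.ld_block_scale, rng)
    hap_cult = simulate_haplotypes(p_cult, chrom, pos, 2 * config.n_cult,
                                   config.ld_block_scale, rng)
    hap_cult = apply_sweeps(hap_cult, chrom, pos, config, rng)

    dos_wild = (hap_wild[0::2] + hap_wild[1::2]).astype(np.int8)  # (n_wild, S)
    dos_cult = (hap_cult[0::2] + hap_cult[1::2]).astype(np.int8)
    true_dosage = np.vstack([dos_wild, dos_cult]).T  # sites x samples
    ad_ref, ad_alt = simulate_reads_and_genotypes(true_dosage, config, rng)
    called = call_genotype_from_depths(ad_ref, ad_alt)

    genome = _simulate_genome(config, rng)
    ref = np.asarray([genome[c][p - 1].decode() for c, p in zip(chrom, pos)], dtype=object)
    others = {"A": "G", "C": "T", "G": "A", "T": "C"}  # deterministic transition alt
    alt = np.asarray([others[r] for r in ref], dtype=object)

    samples = config.wild_samples + config.cult_samples
    matrix = GenotypeMatrix(chrom=chrom, pos=pos, ref=ref, alt=alt,
                            dosage=called, samples=samples,
                            ad_ref=ad_ref, ad_alt=ad_alt)

    causal = config.causal_site_index
    if causal is None and config.effect_size != 0:
        causal = pick_causal_site(chrom, pos, dos_cult.T, config)
    y = simulate_phenotype(dos_cult.T, causal, config, rng)
    phenotype = dict(zip(config.cult_samples, (float(v) for v in y)))

    truth = SimTruth(
        sweep_regions=[Region(sw.chrom, sw.start, sw.end, sw.intensity)
                       for sw in config.sweeps],
        p_anc=p_anc, p_wild=p_wild, p_cult=p_cult,
        causal_site_index=causal,
        hap_wild=hap_wild, hap_cult=hap_cult,
    )
    return Simulation(config=config, truth=truth, matrix=matrix,
                      true_dosage=true_dosage, phenotype=phenotype, genome=genome)


def write_outputs(sim: Simulation, out_dir) -> dict[str, Path]:
    """Write VCF, GFF3, FASTA, phenotype TSV, sample table and truth BED."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "variants.vcf",
        "gff": out / "genes.gff3",
        "fasta": out / "genome.fa",
        "phenotype": out / "phenotype.tsv",
        "samples": out / "samples.tsv",
        "truth_bed": out / "truth_sweeps.bed",
    }
    write_vcf(sim.matrix, paths["vcf"], contig_lengths=sim.config.chrom_lengths)

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        for gi, (c, s, e) in enumerate(sim.config.genes()):
            strand = "+" if gi % 2 == 0 else "-"
            gid = f"gene{gi + 1:05d}"
            fh.write(f"{c}\tsim\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gid}\n")
            fh.write(f"{c}\tsim\tmRNA\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gid}.t1;Parent={gid}\n")
            fh.write(f"{c}\tsim\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\tID={gid}.cds;Parent={gid}.t1\n")

    with open(paths["fasta"], "w") as fh:
        for c, seq in sim.genome.items():
            fh.write(f">{c}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), 80):
                fh.write(raw[i:i + 80] + "\n")

    with open(paths["phenotype"], "w") as fh:
        fh.write("sample\tdays\n")
        for s, v in sim.phenotype.items():
            fh.write(f"{s}\t{v:.4f}\n")

    sim.sample_table.to_tsv(paths["samples"])

    with open(paths["truth_bed"], "w") as fh:
        for r in sim.truth.sweep_regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    return paths
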