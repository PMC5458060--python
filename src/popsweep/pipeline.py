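"""End-to-end orchestration: simulate (or load), filter, scan, associate.

This is the glue the command-line interface and the reproduction script use.
Every stage writes plain-text artefacts (BedGraph/BED/TSV) so that two runs
with the same configuration can be compared byte for byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import assoc, linkage, popstats, sweepscan, variants
from .simulate import SimConfig, Simulation, simulate as _simulate, write_outputs as _write_outputs

logger = logging.getLogger("popsweep")

#: pipeline-scale LD settings: decay is measured within 100 kb which is far
#: beyond the simulated correlation length of a few kb
PIPELINE_LD_MAX_DISTANCE = 100_000


@dataclass
class PipelineResult:
    """Summary quantities of one full run (all computed, nothing cached)."""

    n_sites_vcf: int
    n_sites_support: int
    n_sites_gwas: int
    mean_pi_wild: float
    mean_pi_cult: float
    mean_fst: float
    fst_top1_threshold: float
    n_fst_regions: int
    n_fst_genes: int
    ld_decay_wild_bp: float | None
    ld_decay_cult_bp: float | None
    omega: float
    n_sweep_regions: int
    sweep_span_bp: int
    sweep_recovery: float  # fraction of planted sweeps overlapped by a call
    called_span_ratio: float  # called span / planted span
    causal_p: float | None
    causal_hit: bool | None
    n_gwas_significant: int


def run_pipeline(config: SimConfig, out_dir, k_pca: int = 10,
                 gwas_alpha: float = 1e-4) -> PipelineResult:
    """Simulate, write files, then run every analysis stage from the files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = _simulate(config)
    paths = _write_outputs(sim, out)

    matrix = variants.read_vcf(paths["vcf"])
    table = variants.SampleTable.from_tsv(paths["samples"])
    table.validate(matrix)
    lengths = dict(config.chrom_lengths)

    matrix_support, n_dropped_support = variants.filter_site_support(matrix)
    matrix_gwas, _ = variants.filter_maf_missing(matrix_support)

    spec = popstats.WindowSpec()
    pi_wild = popstats.windowed_pi(matrix_support, table, variants.WILD, spec, chrom_lengths=lengths)
    pi_cult = popstats.windowed_pi(matrix_support, table, variants.CULTIVATED, spec, chrom_lengths=lengths)
    ratio = popstats.pi_ratio(pi_wild, pi_cult)
    fst = popstats.windowed_fst(matrix_support, table, (variants.WILD, variants.CULTIVATED),
                                spec, chrom_lengths=lengths)
    fst_regions = popstats.top_quantile_regions(fst, 0.01)
    fst_thr = popstats.quantile_threshold(fst.value[fst.defined], 0.01)
    fst_genes = popstats.genes_in_regions(fst_regions, paths["gff"])

    pi_wild.to_bedgraph(out / "pi_wild.bedgraph")
    pi_cult.to_bedgraph(out / "pi_cult.bedgraph")
    fst.to_bedgraph(out / "fst.bedgraph")
    popstats.write_regions_bed(fst_regions, out / "fst_top1_regions.bed")

    ld_cfg = linkage.LDConfig(max_distance=PIPELINE_LD_MAX_DISTANCE)
    decay_bp = {}
    for pop, tag in ((variants.WILD, "wild"), (variants.CULTIVATED, "cult")):
        curve = linkage.ld_decay(matrix_support, table, pop, ld_cfg)
        curve.to_tsv(out / f"ld_decay_{tag}.tsv")
        decay_bp[tag] = linkage.decay_distance(curve, threshold=0.2)

    model = sweepscan.SweepModel()
    clr, omega = sweepscan.scan_genome(
        matrix_support, table, reference=variants.WILD, objective=variants.CULTIVATED,
        model=model, chrom_lengths=lengths,
    )
    clr_windows = sweepscan.tabulate_windows(clr, chrom_lengths=lengths)
    sweeps = sweepscan.call_sweeps(clr_windows, ratio)
    clr_windows.to_bedgraph(out / "clr_windows.bedgraph")
    popstats.write_regions_bed(sweeps, out / "sweep_regions.bed")

    pheno = assoc.read_phenotype_tsv(paths["phenotype"])
    gwas = assoc.gwas_scan(matrix_gwas, pheno, k=min(k_pca, len(pheno) - 2), alpha=gwas_alpha)
    gwas.to_tsv(out / "gwas.tsv")

    planted = sim.truth.sweep_regions
    recovered = sum(
        1 for t in planted
        if any(r.overlaps(t.chrom, t.start, t.end) for r in sweeps)
    )
    planted_span = sum(r.span for r in planted)
    called_span = sum(r.span for r in sweeps)

    causal_p = None
    causal_hit = None
    if sim.truth.causal_site_index is not None:
        causal_p, causal_hit = causal_signal(sim, matrix_gwas, gwas)

    result = PipelineResult(
        n_sites_vcf=matrix.n_sites,
        n_sites_support=matrix_support.n_sites,
        n_sites_gwas=matrix_gwas.n_sites,
        mean_pi_wild=popstats.mean_pi(pi_wild),
        mean_pi_cult=popstats.mean_pi(pi_cult),
        mean_fst=popstats.mean_fst(matrix_support, table, (variants.WILD, variants.CULTIVATED)),
        fst_top1_threshold=fst_thr,
        n_fst_regions=len(fst_regions),
        n_fst_genes=sum(len(g) for g in fst_genes),
        ld_decay_wild_bp=decay_bp["wild"],
        ld_decay_cult_bp=decay_bp["cult"],
        omega=omega,
        n_sweep_regions=len(sweeps),
        sweep_span_bp=called_span,
        sweep_recovery=recovered / len(planted) if planted else float("nan"),
        called_span_ratio=called_span / planted_span if planted_span else float("nan"),
        causal_p=causal_p,
        causal_hit=causal_hit,
        n_gwas_significant=int(gwas.significant.sum()),
    )
    with open(out / "summary.json", "w") as fh:
        json.dump({k: _jsonable(v) for k, v in vars(result).items()}, fh, indent=2, sort_keys=True)
    return result


def causal_signal(sim: Simulation, matrix_gwas, gwas: assoc.AssocResult,
                  r2_partner: float = 0.5):
    """P-value at the causal SNP and whether it (or an r2 > ``r2_partner``
    LD partner) is flagged significant."""
    ci = sim.truth.causal_site_index
    c_chrom = str(sim.matrix.chrom[ci])
    c_pos = int(sim.matrix.pos[ci])
    cult = [s for s in sim.sample_table.members(variants.CULTIVATED) if s in matrix_gwas.samples]
    sub = matrix_gwas.take_samples(cult)
    causal_dosage = sim.true_dosage[ci][[sim.matrix.samples.index(s) for s in cult]]
    hit = False
    causal_p = None
    for i in np.flatnonzero(gwas.significant):
        if str(matrix_gwas.chrom[i]) != c_chrom:
            continue
        r2 = linkage.r2_pair(causal_dosage, sub.dosage[i])
        if np.isfinite(r2) and (r2 > r2_partner or int(matrix_gwas.pos[i]) == c_pos):
            hit = True
            break
    exact = np.flatnonzero((matrix_gwas.chrom == c_chrom) & (matrix_gwas.pos == c_pos))
    if len(exact):
        causal_p = float(gwas.p[exact[0]])
    return causal_p, hit


def _jsonable(v):
    if v is None or isinstance(v, (int, float, bool, str)):
        return v
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return str(v)
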