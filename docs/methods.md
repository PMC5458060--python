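# Methods

`popsweep` re-implements, as a tested pipeline, the population-genomic
workflow used to characterise crop domestication from transcriptome-derived
SNPs: genotype-evidence filtering, windowed diversity and differentiation,
LD decay, a cross-population composite-likelihood (XP-CLR-style) sweep scan
with quantile-based region calling, and a stratification-corrected
quantitative-trait association scan. Everything is exercised end-to-end on a
synthetic two-population dataset whose statistical structure is under full
control, so each stage has a closed-form or brute-force oracle.

## The synthetic study design

The generator models a wild-progenitor panel against a cultivated panel that
diverged under pure drift with a weak domestication bottleneck.

**Allele frequencies** follow a hierarchical Balding–Nichols model: per site
an ancestral frequency `p_anc ~ Uniform(0.05, 0.95)`, and each population
drifts to `p_P ~ Beta(p_anc(1-F)/F, (1-p_anc)(1-F)/F)`, which has mean
`p_anc` and variance `F·p_anc(1-p_anc)`. The bottleneck is encoded as
`F_cult (0.10) > F_wild (0.05)`. This closed form is what makes the drift
variance ω and the Weir–Cockerham FST testable against exact expectations —
the reason it was chosen over a coalescent simulator.

**Haplotypes** are drawn by a Markov copying scheme. Each haplotype carries a
latent uniform `u`; at each site, with probability `exp(-Δbp/λ)` (λ =
`ld_block_scale` = 2 kb) the previous site's `u` is reused, otherwise a fresh
uniform is drawn, and the allele is `u < p_site`. Marginals are exactly
Bernoulli(`p_site`) while the correlation between sites decays roughly as
`exp(-d/λ)`. Because alleles are thresholded through site-specific
frequencies, r² between sites of unequal frequency is below the copying
correlation, so the empirical r²=0.2 decay distance is shorter than λ
(≈0.7–1.4 kb at λ = 2 kb). The model produces LD decay on the kb scale that
real transcriptome panels show, but not the population-specific decay
ordering caused by demography.

**Sweeps** are planted at the haplotype level: inside each 50-kb sweep
interval a cultivated haplotype is "swept" with probability `intensity`
(default 0.9) and then carries the alt allele at every interior site;
escapes keep their neutral alleles. This mirrors the hitchhiking-with-escape
mixture the scan's alternative model assumes. With per-haplotype escape at
rate 0.1 the residual heterozygosity inside a sweep is `E[2q(1-q)]` with
`q = 0.1(1-p)`, about 30% of the genome background — a strong but not total
diversity crater (total fixation requires intensity 1).

**Read evidence.** Per genotype, depth ~ Poisson(20), alt reads ~
Binomial(depth, dosage/2), and 5% of entries are masked. VCF genotypes are
then *re-called* from the depths with the evidence rule below, so the
written files exercise the same calling path as real data would.

**Phenotype.** Bolting days for the cultivated accessions:
`y = 50 + 5·dosage(causal SNP) + N(0, 2²)` (days). The causal SNP defaults
to the first cultivated-polymorphic site (MAF ≥ 0.2) outside every sweep,
chosen deterministically so the recovery target is reproducible. Association
experiments use a cohort of 59 phenotyped accessions, the size at which the
trait scan is well powered at the fixed `P < 1e-4` threshold.

The genome FASTA is generated with stop-free codon structure inside the gene
models (start codon, sense codons, stop), alternating strands, so codon
degeneracy and coding-effect annotation run cleanly on simulated output. All
randomness flows from one integer seed through a single generator; identical
configurations produce byte-identical files.

## Genotype evidence and site filters

A genotype call requires at least 3 reads in total, and each called allele
must be supported at a within-genotype frequency strictly above 25%: both
above → heterozygote, otherwise the majority-allele homozygote (an allele at
exactly 25% is not called — the inequality is strict). At the site level, a
SNP is kept only if at least one sample carries ≥3 alt-supporting reads.
The association SNP set additionally requires minor allele frequency > 5%
and missingness < 10% (both strict). The 90%-genotyped rule for diversity is
applied panel-wide (all accessions), not per population: with an 8-sample
wild panel a per-population reading would demand every wild sample be
genotyped and bias wild diversity downward.

## Diversity and differentiation

Per-site diversity is the mean pairwise allele difference
`π = c₁(n-c₁)/C(n,2)` over the `n` observed alleles. Windowed π sums site
values over 10-kb windows sliding by 1 kb (grid anchored at 0, last partial
window kept with the full-size denominator) and divides by the window span
in bp — monomorphic positions contribute zero. The window-span denominator
is used rather than a "callable-span" denominator, which is ill-defined for
transcriptome data; the `min_genotyped` argument exposes the site-filtering
knob.

FST uses the Weir–Cockerham (1984) variance components (a: between
populations, b: between individuals within populations, c: within
individuals) computed per site from sample sizes, allele frequencies and
observed heterozygosities; window values are ratios of sums
`Σa / Σ(a+b+c)`. Negative per-site components are retained in the sums.

Outlier regions take the top fraction of defined window values: the
threshold is the ascending order statistic at rank `ceil((1-f)·m)`, ties
included above-or-equal, and passing windows that overlap or abut merge into
regions scored by their best window. One guard: when the tie mass at the
threshold inflates the passing fraction beyond twice the requested one (a
degenerate spike, e.g. a score floored at zero across most of the genome),
the cut switches to strictly-greater; a constant track therefore yields no
regions.

## Linkage disequilibrium

Two-locus r² comes from EM-estimated haplotype frequencies (50 iterations or
Δ < 1e-8); the double heterozygote is the only phase-ambiguous cell. Sites
enter the decay curve after a MAF > 0.05 filter and a conditional exact
Hardy–Weinberg test (drop p < 0.001). The HWE p-value enumerates all
heterozygote counts compatible with the observed allele counts and sums the
probabilities of tables no more probable than the observed one (two-sided,
no mid-p) — conservative by construction. All within-chromosome pairs up to
`max_distance` (1 Mb by default, following the convention that the upstream
tool's `maxdistance 1000` is in kb) are binned by physical distance (1-kb
bins); the decay distance is where linear interpolation between adjacent bin
means first crosses r² = 0.2 from above. The end-to-end pipeline restricts
pairs to 100 kb since the simulated correlation length is a few kb.

## The sweep scan

At SNPs with reference (wild) frequency `p0` and objective (cultivated)
counts `x` of `n`, two models are contrasted:

* **Drift null.** The latent objective frequency `q` is normal with mean
  `p0` and variance `ω·p0(1-p0)`, censored to [0, 1] with the tail masses
  placed as point masses at 0 and 1 (fixation/loss). The observation is
  Binomial(n, q), marginalised over a 512-cell discretisation of the latent
  law. Exact scalar evaluations place each cell's mass at its
  conditional-mean representative, so the ω→0 limit recovers the binomial
  log-pmf to <1e-6; the genome scan uses midpoint representatives on a
  shared grid, which lets SNPs with equal (x, n) share one kernel. Masses
  come from CDF differences, so likelihoods sum to 1 over x to machine
  precision at any grid size, and refining 512→4096 cells moves
  log-likelihoods by ≪1e-4 at realistic ω.
* **Hitchhiking alternative.** A lineage escapes the sweep with probability
  `c = 1 - exp(-d·ln(2N_e s)/s)` (genetic distance d to the putative
  selected site, selection coefficient s, `N_e` = 10,000; c = 1 when
  `2N_e·s ≤ 1`). Given pre-sweep frequency `q` from the same drift law, the
  post-sweep frequency is `1 - c(1-q)` with probability `q` (the favoured
  mutation arose on the background of the tracked allele) and `c·q`
  otherwise. At c = 1 this reduces to the null *exactly* (same grid cells),
  which keeps the composite likelihood ratio non-negative once the no-sweep
  model is included in the maximisation. An earlier formulation that jumped
  the latent frequency to a near-fixation point mass was rejected: it
  assigns essentially zero likelihood to partially swept SNPs, which are
  exactly what per-haplotype escape produces, and it collapses the neutral
  score distribution to a point.

At each grid point (every 100 bp) the scan collects SNPs within ±0.00025
Morgans (half of the 0.0005-Morgan window; at the 1 cM/Mb fallback rate this
is ±25 kb), keeps at most 100 nearest, down-weights each SNP by 1/m where m
counts window SNPs with reference-population r² > 0.7 against it (including
itself), and reports `CLR = 2·max_s Σ wᵢ·[log L_sweep(c(dᵢ,s)) - log L_null]`
over a 15-point log grid of s ∈ [1e-4, 0.5], floored at 0 where the null
wins. Genetic positions come from piecewise-linear interpolation of a
physical↔genetic anchor map when one is supplied, else the uniform fallback
rate. For speed the scan tabulates each SNP's log-ratio on a fixed 76-point
escape-probability grid (log-dense near both ends) and interpolates linearly
in c; `clr_at_gridpoint` uses the same tables, while `null_loglik` /
`sweep_loglik` are the exact scalar references.

ω is estimated genome-wide by the method of moments,
`ω = mean[( p̂_obj - p_ref )² - p̂_obj(1-p̂_obj)/n_obj] / [p_ref(1-p_ref)]`,
which subtracts objective-sample binomial noise but deliberately absorbs
reference-sample noise and reference drift — a conservative null for the
scan. SNPs monomorphic in the reference sample are dropped (the null
requires 0 < p0 < 1).

Scores are tabulated as the maximum CLR per non-overlapping 10-kb window.
Region calling follows the published recipe: threshold at the top 3% of
window values, merge adjacent passing windows (score = best window), keep
regions reaching the top-1% window level, and drop regions that do not
overlap (≥1 bp) any window in the top half of the π_wild/π_cult ratio. The
top-1% cut is applied on the window-value scale; region-level application is
a one-line change and is not the default.

## Stratification-corrected association

Genotypes are normalised the EIGENSTRAT way (impute missing to the site
mean, centre, divide by `sqrt(p̂(1-p̂))`, `p̂` = mean dosage/2; monomorphic
sites dropped — note the column variance under HWE is then 2, since
`Var(dosage) = 2p(1-p)`). The top k = 10 eigenvectors of the sample
covariance capture structure; both genotype and phenotype are residualised
on intercept + axes by exact OLS projection (idempotent), and the statistic
is `(n-k-1)·ρ²` against χ²₁, the quantitative-trait analogue of the
Armitage-trend correction. Significance is the fixed threshold `P < 1e-4`
with no multiple-testing correction and no genomic-control rescaling.
Bolting days enter untransformed.

## Problem sizes and defaults

The default simulation is 2 chromosomes × 5 Mb, 20,000 genic SNPs, 8 wild +
30 cultivated accessions, three 50-kb sweeps at intensity 0.9, mean depth
20×, 5% missingness — the scale at which the full pipeline (simulation,
filtering, diversity, FST, LD, scan, GWAS) runs in well under a minute and
every planted sweep is recoverable. Association experiments use 59
phenotyped cultivated accessions. The reproduction script
(`scripts/acceptance.py`) re-runs all of this from a single seed.

## What the tests do and do not show

Passing tests establish that each estimator matches an independent oracle
(all-pairs π, a literal Weir–Cockerham transcription, exhaustive HWE
enumeration, dense-grid likelihood integration), that the scan recovers
planted sweeps with bounded over-call under the generator's drift + copying
model, and that the association scan is calibrated on a structured null.
They do not show robustness to demographic histories outside Balding–Nichols
drift (migration, admixture, growth), to ascertainment beyond genic
placement, or to genotyping error models other than Poisson/Binomial read
sampling; real-data behaviour of the region-calling quantiles also depends
on genome-wide score distributions the simulator only roughly reproduces.

## Known limitations

* The scan's composite likelihood treats SNPs as exchangeable given the
  escape probability; the 1/m down-weighting is a heuristic for redundancy,
  not a likelihood correction.
* ω is a single genome-wide scalar; locally varying drift (e.g. low-
  recombination regions) will mis-calibrate the null there.
* The exact conditional HWE test and EM r² assume biallelic diploid
  genotypes; multi-allelic records are skipped at VCF ingestion.
* Sample sizes below ~4 haplotypes per population leave most statistics
  undefined and are rejected rather than extrapolated.
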