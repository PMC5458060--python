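"""Genotype containers, VCF I/O, evidence filters and site-class annotation.

The variant set entering the analyses is a matrix of biallelic SNP genotypes
(alt-allele dosage 0/1/2, or missing) with optional per-sample allele depths
carried along from the caller.  Genotype evidence rules operate on those
depths: a genotype needs at least ``MIN_READS`` supporting reads in total and
each called allele must be seen at a within-genotype frequency strictly above
``MIN_ALLELE_FRACTION``.  Site-level filters (alt-read support, minor allele
frequency, missingness) and codon-degeneracy / coding-effect annotation from
GFF3 + FASTA gene models complete the module.

Internal coordinates are 0-based half-open; VCF and GFF3 are 1-based at the
boundary and the conversion happens only in the readers/writers here.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

logger = logging.getLogger("popsweep")

#: dosage code for a missing genotype
MISSING: int = -1
#: minimum total reads required to call a genotype
MIN_READS: int = 3
#: within-genotype allele fraction that must be exceeded for an allele call
MIN_ALLELE_FRACTION: float = 0.25

WILD = "wild_progenitor"
CULTIVATED = "cultivated"
OTHER = "other"

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid ('*' for stop), standard nuclear code
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
for _stop in _STANDARD_TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

NONCODING = "noncoding"
SYNONYMOUS = "synonymous"
NONSYNONYMOUS = "nonsynonymous"
START_STOP = "start/stop-affecting"
SPLICE_SITE = "splice-site"


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes: sites x samples alt-allele dosages.

    ``dosage`` holds 0/1/2 or :data:`MISSING`; ``ad_ref``/``ad_alt`` are the
    per-genotype allele depths when the VCF carried an AD field.  ``pos`` is
    1-based as in VCF and strictly increasing within each chromosome.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    samples: list[str]
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.ndim != 2 or self.dosage.shape[0] != self.pos.shape[0]:
            raise ValueError("dosage must be (n_sites, n_samples)")
        if self.dosage.shape[1] != len(self.samples):
            raise ValueError("sample count mismatch")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage codes must be 0/1/2 or missing")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def has_depths(self) -> bool:
        return self.ad_ref is not None and self.ad_alt is not None

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset sites by boolean mask or integer index (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[index],
            samples=list(self.samples),
            ad_ref=None if self.ad_ref is None else self.ad_ref[index],
            ad_alt=None if self.ad_alt is None else self.ad_alt[index],
        )

    def take_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosage=self.dosage[:, idx],
            samples=list(names),
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, idx],
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, idx],
        )

    def sample_indices(self, names: Sequence[str]) -> np.ndarray:
        return np.asarray([self.samples.index(s) for s in names], dtype=np.intp)

    def alt_freq(self, sample_names: Sequence[str] | None = None) -> np.ndarray:
        """Per-site alt-allele frequency over non-missing genotypes (NaN if none)."""
        d = self.dosage if sample_names is None else self.dosage[:, self.sample_indices(sample_names)]
        ok = d != MISSING
        n_alleles = 2 * ok.sum(axis=1)
        alt = np.where(ok, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)


@dataclass
class SampleTable:
    """Accession -> population labels with optional per-sample exclusion."""

    population: dict[str, str]
    excluded: set[str] = field(default_factory=set)

    @classmethod
    def from_tsv(cls, path) -> "SampleTable":
        pops: dict[str, str] = {}
        excl: set[str] = set()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                pops[parts[0]] = parts[1]
                if len(parts) > 2 and parts[2].lower() in ("1", "true", "yes", "exclude"):
                    excl.add(parts[0])
        return cls(pops, excl)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, p in self.population.items():
                fh.write(f"{s}\t{p}\t{int(s in self.excluded)}\n")

    def members(self, pop: str) -> list[str]:
        """Samples of a population, excluded accessions removed."""
        return [s for s, p in self.population.items() if p == pop and s not in self.excluded]

    def validate(self, matrix: GenotypeMatrix, populations: Iterable[str] = (WILD, CULTIVATED)) -> None:
        for s in matrix.samples:
            if s not in self.population:
                raise ValueError(f"sample {s!r} missing from sample table")
        for pop in populations:
            if len([s for s in self.members(pop) if s in matrix.samples]) < 2:
                raise ValueError(f"population {pop!r} needs >=2 samples")


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_vcf(path, sample_table: SampleTable | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; indels and multi-allelic records are skipped.

    GT is parsed into dosages, AD into allele-depth matrices when present;
    ``./.`` genotypes become :data:`MISSING`.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # malformed header
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    chrom, pos, ref, alt = [], [], [], []
    dosage_rows, adr_rows, ada_rows = [], [], []
    skipped = 0
    any_ad = False
    for i, v in enumerate(vcf):
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        dosage_rows.append(g)
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None:
            ad = np.asarray(ad)
            ad = np.where(ad < 0, 0, ad)
            adr_rows.append(ad[:, 0].astype(np.int32))
            ada_rows.append(ad[:, 1].astype(np.int32))
            any_ad = True
        else:
            adr_rows.append(np.zeros(len(samples), np.int32))
            ada_rows.append(np.zeros(len(samples), np.int32))
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    n = len(pos)
    mat = GenotypeMatrix(
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        dosage=np.vstack(dosage_rows) if n else np.zeros((0, len(samples)), np.int8),
        samples=samples,
        ad_ref=np.vstack(adr_rows) if (n and any_ad) else None,
        ad_alt=np.vstack(ada_rows) if (n and any_ad) else None,
    )
    if sample_table is not None:
        sample_table.validate(mat, populations=())
    return mat


def write_vcf(matrix: GenotypeMatrix, path, contig_lengths: Mapping[str, int] | None = None) -> None:
    """Write a VCF v4.2 with GT (and AD when depths are present)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if matrix.has_depths:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(matrix.chrom):
                fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.samples) + "\n")
        fmt = "GT:AD" if matrix.has_depths else "GT"
        for i in range(matrix.n_sites):
            fields = [
                str(matrix.chrom[i]), str(matrix.pos[i]), ".", str(matrix.ref[i]),
                str(matrix.alt[i]), ".", "PASS", ".", fmt,
            ]
            for j in range(matrix.n_samples):
                g = gt_strings[int(matrix.dosage[i, j])]
                if matrix.has_depths:
                    g += f":{matrix.ad_ref[i, j]},{matrix.ad_alt[i, j]}"
                fields.append(g)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Genotype evidence and site filters
# ---------------------------------------------------------------------------

def call_genotype_from_depths(ref_reads, alt_reads):
    """Call alt dosage from allele depths; scalar or array, vectorised.

    A genotype needs >= 3 total reads; each allele present in the call must
    be supported at a within-genotype frequency strictly above 25%.  Both
    alleles above the cut -> heterozygote; otherwise the majority-allele
    homozygote (an allele at exactly 25% is not called).
    """
    r = np.asarray(ref_reads)
    a = np.asarray(alt_reads)
    if np.any(r < 0) or np.any(a < 0):
        raise ValueError("read counts must be non-negative")
    total = r + a
    with np.errstate(invalid="ignore", divide="ignore"):
        f_alt = np.where(total > 0, a / np.maximum(total, 1), 0.0)
        f_ref = np.where(total > 0, r / np.maximum(total, 1), 0.0)
    alt_ok = f_alt > MIN_ALLELE_FRACTION
    ref_ok = f_ref > MIN_ALLELE_FRACTION
    out = np.full(total.shape, MISSING, dtype=np.int8)
    out[alt_ok & ref_ok] = 1
    out[alt_ok & ~ref_ok] = 2
    out[~alt_ok & ref_ok] = 0
    out[total < MIN_READS] = MISSING
    if out.ndim == 0:
        return int(out)
    return out


def filter_site_support(matrix: GenotypeMatrix, min_support: int = MIN_READS) -> tuple[GenotypeMatrix, int]:
    """Drop sites where no sample carries >= ``min_support`` alt-supporting reads.

    Returns the filtered matrix and the number of sites dropped.
    """
    if not matrix.has_depths:
        raise ValueError("matrix has no allele depths; skip the support filter for GT-only input")
    keep = (matrix.ad_alt >= min_support).any(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_site_support: dropped %d sites", dropped)
    return matrix.take_sites(keep), dropped


def filter_maf_missing(
    matrix: GenotypeMatrix, maf: float = 0.05, max_missing: float = 0.10
) -> tuple[GenotypeMatrix, int]:
    """Keep sites with minor allele frequency > ``maf`` and missingness < ``max_missing``.

    Both inequalities are strict.  MAF is computed over non-missing alleles.
    """
    if not (0.0 <= maf <= 0.5):
        raise ValueError("maf must be in [0, 0.5]")
    miss = (matrix.dosage == MISSING).mean(axis=1)
    p = matrix.alt_freq()
    with np.errstate(invalid="ignore"):
        m = np.fmin(p, 1.0 - p)
    keep = (m > maf) & (miss < max_missing)
    keep &= ~np.isnan(p)
    dropped = int((~keep).sum())
    return matrix.take_sites(keep), dropped


# ---------------------------------------------------------------------------
# Gene models and codon annotation
# ---------------------------------------------------------------------------

@dataclass
class SiteClass:
    """Per-site codon degeneracy and coding effect.

    ``degeneracy`` is the number of nucleotides at the SNP's codon offset that
    leave the amino acid unchanged (1 = zero-fold, ... 4 = fourfold) or 0 for
    non-coding sites; ``effect`` is one of the effect category strings.
    """

    degeneracy: np.ndarray
    effect: np.ndarray

    @property
    def fourfold(self) -> np.ndarray:
        return self.degeneracy == 4


class _Transcript:
    __slots__ = ("chrom", "strand", "segments", "coding_seq", "pos_to_coding", "introns")

    def __init__(self, chrom, strand, segments, genome_seq):
        # segments: sorted 1-based inclusive (start, end) CDS intervals
        self.chrom = chrom
        self.strand = strand
        self.segments = segments
        plus_seq = "".join(genome_seq[s - 1:e] for s, e in segments)
        positions = np.concatenate([np.arange(s, e + 1) for s, e in segments])
        if strand == "-":
            self.coding_seq = plus_seq.translate(_COMPLEMENT)[::-1]
            positions = positions[::-1]
        else:
            self.coding_seq = plus_seq
        self.pos_to_coding = {int(p): i for i, p in enumerate(positions)}
        self.introns = [
            (segments[k][1] + 1, segments[k + 1][0] - 1)
            for k in range(len(segments) - 1)
            if segments[k + 1][0] - segments[k][1] > 1
        ]


def _load_gene_models(gff_path, fasta_path) -> list[_Transcript]:
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff_path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique"
    )
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    out: list[_Transcript] = []
    parents = list(db.features_of_type("mRNA"))
    if not parents:  # CDS directly under gene
        parents = list(db.features_of_type("gene"))
    for mrna in parents:
        cds = sorted(db.children(mrna, featuretype="CDS"), key=lambda f: f.start)
        if not cds:
            continue
        chrom = cds[0].seqid
        segments = [(f.start, f.end) for f in cds]
        tr = _Transcript(chrom, mrna.strand, segments, str(fasta[chrom][:]))
        if len(tr.coding_seq) % 3 != 0:
            warnings.warn(f"CDS of {mrna.id} not a multiple of 3; skipped")
            continue
        aa = [CODON_TO_AA.get(tr.coding_seq[k:k + 3], "X") for k in range(0, len(tr.coding_seq), 3)]
        if "*" in aa[:-1]:
            warnings.warn(f"internal stop codon in {mrna.id}; gene skipped")
            continue
        out.append(tr)
    return out


def _degeneracy_of(codon: str, offset: int) -> int:
    aa = CODON_TO_AA.get(codon, "X")
    count = 0
    for nt in "ACGT":
        alt_codon = codon[:offset] + nt + codon[offset + 1:]
        if CODON_TO_AA.get(alt_codon, "X") == aa:
            count += 1
    return count


def _annotate(gff_path, fasta_path, matrix: GenotypeMatrix, with_effect: bool) -> SiteClass:
    from pyfaidx import Fasta

    transcripts = _load_gene_models(gff_path, fasta_path)
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    by_chrom: dict[str, list[_Transcript]] = {}
    for tr in transcripts:
        by_chrom.setdefault(tr.chrom, []).append(tr)

    deg = np.zeros(matrix.n_sites, dtype=np.int8)
    effect = np.full(matrix.n_sites, NONCODING, dtype=object)
    mismatches = []
    for i in range(matrix.n_sites):
        chrom, pos = str(matrix.chrom[i]), int(matrix.pos[i])
        ref, alt = str(matrix.ref[i]), str(matrix.alt[i])
        if chrom in fasta and fasta[chrom][pos - 1] != ref:
            mismatches.append(f"{chrom}:{pos} ref={ref} fasta={fasta[chrom][pos - 1]}")
            continue
        for tr in by_chrom.get(chrom, ()):
            ci = tr.pos_to_coding.get(pos)
            if ci is not None:
                codon_idx, off = divmod(ci, 3)
                codon = tr.coding_seq[3 * codon_idx:3 * codon_idx + 3]
                deg[i] = _degeneracy_of(codon, off)
                if with_effect:
                    alt_base = alt.translate(_COMPLEMENT) if tr.strand == "-" else alt
                    alt_codon = codon[:off] + alt_base + codon[off + 1:]
                    ref_aa = CODON_TO_AA.get(codon, "X")
                    alt_aa = CODON_TO_AA.get(alt_codon, "X")
                    if codon_idx == 0 or ref_aa == "*" or alt_aa == "*":
                        effect[i] = START_STOP
                    elif ref_aa == alt_aa:
                        effect[i] = SYNONYMOUS
                    else:
                        effect[i] = NONSYNONYMOUS
                break
            if with_effect and effect[i] == NONCODING:
                for s, e in tr.introns:
                    if s <= pos <= e and (pos - s < 2 or e - pos < 2):
                        effect[i] = SPLICE_SITE
                        break
    if mismatches:
        raise ValueError("SNP ref alleles disagree with FASTA: " + "; ".join(mismatches[:10]))
    return SiteClass(degeneracy=deg, effect=effect)


def annotate_degeneracy(gff_path, fasta_path, matrix: GenotypeMatrix) -> SiteClass:
    """Codon degeneracy per SNP from joined CDS models (strand- and phase-aware).

    Degeneracy is the number of nucleotides at the SNP's within-codon offset
    that encode the same amino acid under the standard nuclear code; 4 marks
    fourfold-degenerate sites.  Sites outside any CDS get 0 / ``noncoding``.
    """
    return _annotate(gff_path, fasta_path, matrix, with_effect=False)


def classify_coding_effect(matrix: GenotypeMatrix, gff_path, fasta_path) -> SiteClass:
    """Coding effect of each SNP's alt allele (synonymous / nonsynonymous /
    start- or stop-affecting / splice-site / noncoding), plus degeneracy."""
    return _annotate(gff_path, fasta_path, matrix, with_effect=True)
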