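import numpy as np
import pytest

import popsweep as ps
from popsweep.pipeline import run_pipeline


@pytest.fixture(scope="session")
def default_config() -> ps.SimConfig:
    """The study-scale default: 2 x 5 Mb, 20k SNPs, 8 wild / 30 cultivated,
    weak bottleneck, three planted 50-kb sweeps at intensity 0.9."""
    return ps.SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_run(default_config, tmp_path_factory):
    """One full pipeline run on the default simulation, shared by the
    recovery and determinism checks."""
    out = tmp_path_factory.mktemp("default_run")
    result = run_pipeline(default_config, out)
    return default_config, out, result


@pytest.fixture(scope="session")
def small_sim():
    """A 1-Mb single-chromosome simulation with one planted sweep."""
    cfg = ps.SimConfig(
        n_sites=2_000,
        chrom_lengths={"chr1": 1_000_000},
        sweeps=(ps.SweepSpec("chr1", 400_000, 450_000, 0.9),),
        seed=17,
    )
    return ps.simulate(cfg)


def write_toy_gene(tmp_path, cds: str, strand: str = "+", name: str = "g1",
                   flank: str = "ACGTACGTAC", intron_at: int | None = None,
                   intron_seq: str = "GTAAGTTTAG"):
    """Write a one-gene FASTA + GFF3; returns (fasta, gff, cds_genome_start).

    ``cds`` is the coding-strand sequence.  With ``intron_at`` the CDS is
    split at that coding offset by ``intron_seq``.  The genome carries the
    plus-strand image (reverse-complemented for '-' genes).
    """
    comp = str.maketrans("ACGT", "TGCA")

    def plus_image(seq):
        return seq.translate(comp)[::-1] if strand == "-" else seq

    if intron_at is None:
        segments = [cds]
    else:
        segments = [cds[:intron_at], cds[intron_at:]]
    if strand == "-":
        genomic = plus_image(cds) if intron_at is None else None
        if genomic is None:
            # on the minus strand the second coding segment sits first in
            # genome coordinates
            genomic = plus_image(segments[1]) + intron_seq + plus_image(segments[0])
    else:
        genomic = segments[0] + (intron_seq if intron_at is not None else "") + (
            segments[1] if intron_at is not None else "")
    seq = flank + genomic + flank
    start = len(flank) + 1  # 1-based genomic start of the gene span
    end = len(flank) + len(genomic)

    fasta = tmp_path / "toy.fa"
    fasta.write_text(">chrT\n" + seq + "\n")
    gff = tmp_path / "toy.gff3"
    lines = ["##gff-version 3",
             f"chrT\ttoy\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={name}",
             f"chrT\ttoy\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={name}.t;Parent={name}"]
    if intron_at is None:
        lines.append(f"chrT\ttoy\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID={name}.c;Parent={name}.t")
    else:
        lens = [len(s) for s in segments]
        if strand == "+":
            s1, e1 = start, start + lens[0] - 1
            s2 = e1 + len(intron_seq) + 1
            e2 = s2 + lens[1] - 1
        else:
            s1, e1 = start, start + lens[1] - 1  # second coding segment first
            s2 = e1 + len(intron_seq) + 1
            e2 = s2 + lens[0] - 1
        for s_, e_ in ((s1, e1), (s2, e2)):
            lines.append(f"chrT\ttoy\tCDS\t{s_}\t{e_}\t.\t{strand}\t0\tID={name}.c;Parent={name}.t")
    gff.write_text("\n".join(lines) + "\n")
    return fasta, gff, start


def matrix_for_positions(fasta, positions, alts=None, n_samples=2):
    """GenotypeMatrix with ref alleles taken from the FASTA at ``positions``."""
    from pyfaidx import Fasta

    fa = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
    seq = str(fa["chrT"][:])
    others = {"A": "G", "C": "T", "G": "A", "T": "C"}
    refs = [seq[p - 1] for p in positions]
    alts = alts or [others[r] for r in refs]
    return ps.GenotypeMatrix(
        chrom=np.array(["chrT"] * len(positions), dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        dosage=np.zeros((len(positions), n_samples), dtype=np.int8),
        samples=[f"s{i}" for i in range(n_samples)],
    )
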