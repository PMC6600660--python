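"""Shared fixtures: tiny hand-written annotations and simulated datasets."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pytest

from microexon import synthetic_data as sim

# hand-built toy: one gene, two transcripts, seven exon features (five
# distinct intervals), one 12-nt micro-exon shared by both transcripts.
TOY_GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    chrT\ttoy\tgene\t1\t600\t.\t+\t.\tID=geneA
    chrT\ttoy\tmRNA\t1\t600\t.\t+\t.\tID=tA1;Parent=geneA
    chrT\ttoy\texon\t1\t100\t.\t+\t.\tID=tA1.e1;Parent=tA1
    chrT\ttoy\texon\t201\t212\t.\t+\t.\tID=tA1.e2;Parent=tA1
    chrT\ttoy\texon\t301\t400\t.\t+\t.\tID=tA1.e3;Parent=tA1
    chrT\ttoy\texon\t501\t600\t.\t+\t.\tID=tA1.e4;Parent=tA1
    chrT\ttoy\tCDS\t31\t100\t.\t+\t0\tID=tA1.c1;Parent=tA1
    chrT\ttoy\tCDS\t201\t212\t.\t+\t2\tID=tA1.c2;Parent=tA1
    chrT\ttoy\tCDS\t301\t390\t.\t+\t2\tID=tA1.c3;Parent=tA1
    chrT\ttoy\tmRNA\t1\t400\t.\t+\t.\tID=tA2;Parent=geneA
    chrT\ttoy\texon\t1\t100\t.\t+\t.\tID=tA2.e1;Parent=tA2
    chrT\ttoy\texon\t201\t212\t.\t+\t.\tID=tA2.e2;Parent=tA2
    chrT\ttoy\texon\t301\t400\t.\t+\t.\tID=tA2.e3;Parent=tA2
    """
)


def _toy_fasta_text() -> str:
    import random

    rng = random.Random(42)
    seq = "".join(rng.choice("ACGT") for _ in range(700))
    return ">chrT\n" + "\n".join(seq[i : i + 80] for i in range(0, 700, 80)) + "\n"


@pytest.fixture(scope="session")
def toy_annotation(tmp_path_factory) -> tuple[Path, Path]:
    d = tmp_path_factory.mktemp("toy")
    gff = d / "toy.gff3"
    fasta = d / "toy.fa"
    gff.write_text(TOY_GFF3)
    fasta.write_text(_toy_fasta_text())
    return gff, fasta


@pytest.fixture(scope="session")
def small_truth() -> sim.GroundTruth:
    cfg = sim.SimConfig(seed=5, n_genes=15, depth=40, n_tissues=2, n_replicates=2)
    return sim.simulate_genome_annotation(cfg)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_truth) -> Path:
    d = tmp_path_factory.mktemp("fixture")
    sim.write_genome_fasta(small_truth.genome, d / "genome.fa")
    sim.write_gff3(small_truth, d / "annotation.gff3")
    return d
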