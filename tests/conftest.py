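import textwrap

import pytest

TOY_GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    chr1\ttoy\tgene\t1001\t1900\t.\t+\t.\tID=g1
    chr1\ttoy\tmRNA\t1001\t1900\t.\t+\t.\tID=g1.t1;Parent=g1
    chr1\ttoy\texon\t1001\t1900\t.\t+\t.\tParent=g1.t1
    chr1\ttoy\tCDS\t1001\t1900\t.\t+\t0\tID=g1.t1.cds;Parent=g1.t1
    chr1\ttoy\tgene\t5001\t6500\t.\t-\t.\tID=g2
    chr1\ttoy\tmRNA\t5001\t6500\t.\t-\t.\tID=g2.t1;Parent=g2
    chr1\ttoy\texon\t5001\t5300\t.\t-\t.\tParent=g2.t1
    chr1\ttoy\texon\t5601\t5900\t.\t-\t.\tParent=g2.t1
    chr1\ttoy\texon\t6201\t6500\t.\t-\t.\tParent=g2.t1
    chr1\ttoy\tCDS\t5001\t5300\t.\t-\t0\tID=g2.t1.cds;Parent=g2.t1
    chr1\ttoy\tCDS\t5601\t5900\t.\t-\t0\tID=g2.t1.cds;Parent=g2.t1
    chr1\ttoy\tCDS\t6201\t6500\t.\t-\t0\tID=g2.t1.cds;Parent=g2.t1
    MT\ttoy\tgene\t101\t700\t.\t+\t.\tID=g3
    MT\ttoy\tmRNA\t101\t700\t.\t+\t.\tID=g3.t1;Parent=g3
    MT\ttoy\texon\t101\t700\t.\t+\t.\tParent=g3.t1
    MT\ttoy\tCDS\t101\t700\t.\t+\t0\tID=g3.t1.cds;Parent=g3.t1
    scaffold_77\ttoy\tgene\t201\t800\t.\t+\t.\tID=g4
    scaffold_77\ttoy\tmRNA\t201\t800\t.\t+\t.\tID=g4.t1;Parent=g4
    scaffold_77\ttoy\texon\t201\t800\t.\t+\t.\tParent=g4.t1
    scaffold_77\ttoy\tCDS\t201\t800\t.\t+\t0\tID=g4.t1.cds;Parent=g4.t1
    chr1\ttoy\tgene\t1001\t1900\t.\t+\t.\tID=g5
    chr1\ttoy\tmRNA\t1001\t1900\t.\t+\t.\tID=g5.t1;Parent=g5
    chr1\ttoy\texon\t1001\t1900\t.\t+\t.\tParent=g5.t1
    chr1\ttoy\tCDS\t1001\t1900\t.\t+\t0\tID=g5.t1.cds;Parent=g5.t1
    """
)


@pytest.fixture()
def toy_gff3(tmp_path):
    path = tmp_path / "toy.gff3"
    path.write_text(TOY_GFF3)
    return str(path)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset shared by read-only tests."""
    from igevo import synthdata as sd

    cfg = sd.SimConfig(seed=11, n_chromosomes=2, genes_per_chromosome=40)
    return sd.simulate_dataset(cfg, outdir=None, write_genome_fasta=False)
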