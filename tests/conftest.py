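import textwrap

import pytest


TWO_GENE_GFF = textwrap.dedent(
    """\
    ##gff-version 3
    chr_1\tsrc\tgene\t1\t1200\t.\t+\t.\tID=geneA;Name=geneA
    chr_1\tsrc\tmRNA\t1\t1200\t.\t+\t.\tID=geneA.t1;Parent=geneA
    chr_1\tsrc\tfive_prime_UTR\t1\t100\t.\t+\t.\tID=geneA.t1.u5;Parent=geneA.t1
    chr_1\tsrc\tCDS\t101\t1000\t.\t+\t.\tID=geneA.t1.cds;Parent=geneA.t1
    chr_1\tsrc\tthree_prime_UTR\t1001\t1200\t.\t+\t.\tID=geneA.t1.u3;Parent=geneA.t1
    chr_1\tsrc\tgene\t3001\t5057\t.\t+\t.\tID=geneB;Name=geneB
    chr_1\tsrc\tmRNA\t3001\t5057\t.\t+\t.\tID=geneB.t1;Parent=geneB
    chr_1\tsrc\tfive_prime_UTR\t3001\t3100\t.\t+\t.\tID=geneB.t1.u5;Parent=geneB.t1
    chr_1\tsrc\tCDS\t3101\t5000\t.\t+\t.\tID=geneB.t1.cds;Parent=geneB.t1
    chr_1\tsrc\tthree_prime_UTR\t5001\t5057\t.\t+\t.\tID=geneB.t1.u3;Parent=geneB.t1
    """
)


@pytest.fixture
def two_gene_gff(tmp_path):
    """Hand-built two-gene annotation: 3'UTRs at 1001..1200 and
    5001..5057, i.e. lengths 200 and 57."""
    path = tmp_path / "two_gene.gff3"
    path.write_text(TWO_GENE_GFF)
    return path


@pytest.fixture
def gff_writer(tmp_path):
    def write(text, name="fixture.gff3"):
        path = tmp_path / name
        path.write_text(textwrap.dedent(text))
        return path

    return write
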