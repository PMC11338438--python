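import io

import pytest

from r2d.model import parse_gtf

# Toy transcripts used throughout: TX1 is a 3-exon coding '+' transcript
# (length 350, ORF spanning transcript bases 50..199 stop codon included),
# TX2 a 2-exon noncoding '-' transcript, TX3 a single-exon noncoding one.
TOY_GTF = """\
# toy annotation
chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "TX1"; gene_name "GENE1"; transcript_biotype "protein_coding";
chr1\tt\texon\t301\t450\t.\t+\t.\tgene_id "G1"; transcript_id "TX1"; gene_name "GENE1"; transcript_biotype "protein_coding";
chr1\tt\texon\t601\t700\t.\t+\t.\tgene_id "G1"; transcript_id "TX1"; gene_name "GENE1"; transcript_biotype "protein_coding";
chr1\tt\tCDS\t151\t200\t.\t+\t0\tgene_id "G1"; transcript_id "TX1";
chr1\tt\tCDS\t301\t397\t.\t+\t0\tgene_id "G1"; transcript_id "TX1";
chr1\tt\tstop_codon\t398\t400\t.\t+\t0\tgene_id "G1"; transcript_id "TX1";
chr2\tt\texon\t1001\t1100\t.\t-\t.\tgene_id "G2"; transcript_id "TX2"; gene_name "GENE2"; transcript_biotype "lncRNA";
chr2\tt\texon\t1201\t1300\t.\t-\t.\tgene_id "G2"; transcript_id "TX2"; gene_name "GENE2"; transcript_biotype "lncRNA";
chr3\tt\texon\t501\t800\t.\t+\t.\tgene_id "G3"; transcript_id "TX3";
"""


@pytest.fixture(scope="session")
def toy_annotation():
    return parse_gtf(io.StringIO(TOY_GTF))


@pytest.fixture(scope="session")
def tx1(toy_annotation):
    return toy_annotation.lookup("TX1")


@pytest.fixture(scope="session")
def tx2(toy_annotation):
    return toy_annotation.lookup("TX2")


@pytest.fixture(scope="session")
def tx3(toy_annotation):
    return toy_annotation.lookup("TX3")


@pytest.fixture(scope="session")
def random_annotation():
    """~100 seeded random transcripts (1-10 exons, both strands) for
    oracle-equivalence checks."""
    from r2d.fixtures import FixtureSpec, make_transcriptome

    spec = FixtureSpec(
        n_genes=50,
        isoforms_per_gene=(2, 2),
        exons_per_transcript=(1, 10),
        seed=20260927,
    )
    annotation, _ = make_transcriptome(spec)
    assert len(annotation) >= 100
    return annotation
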