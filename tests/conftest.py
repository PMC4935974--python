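import pytest

from rbpscape.annotation import FeatureRecord, build_annotation


@pytest.fixture
def toy_gene_records():
    """One + strand gene: 5'UTR [0,100), exons [0,100)+[400,500)+[900,1000),
    3'UTR [900,1000); introns [100,400) and [500,900)."""
    return [
        FeatureRecord("chr1", 0, 1000, "+", "gene", "gA"),
        FeatureRecord("chr1", 0, 100, "+", "exon", "gA"),
        FeatureRecord("chr1", 400, 500, "+", "exon", "gA"),
        FeatureRecord("chr1", 900, 1000, "+", "exon", "gA"),
        FeatureRecord("chr1", 0, 100, "+", "five_utr", "gA"),
        FeatureRecord("chr1", 900, 1000, "+", "three_utr", "gA"),
    ]


@pytest.fixture
def toy_annotation(toy_gene_records):
    return build_annotation(toy_gene_records)


@pytest.fixture
def two_gene_annotation(toy_gene_records):
    """Adds a second, minus-strand, intron-rich gene on chr1."""
    records = toy_gene_records + [
        FeatureRecord("chr1", 2000, 12000, "-", "gene", "gB"),
        FeatureRecord("chr1", 2000, 2200, "-", "exon", "gB"),
        FeatureRecord("chr1", 11800, 12000, "-", "exon", "gB"),
        FeatureRecord("chr1", 2000, 2200, "-", "three_utr", "gB"),
        FeatureRecord("chr1", 11800, 12000, "-", "five_utr", "gB"),
    ]
    return build_annotation(records)
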