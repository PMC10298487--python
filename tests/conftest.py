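import pytest

from circkit.annotation import GeneModel
from circkit.catalog import CircRecord
from circkit.simulate import SynthConfig, generate_bundle, simulate_dataset


@pytest.fixture
def two_exon_gene():
    return GeneModel(
        gene_id="HOST1", chromosome="chr1", start=1000, end=2200,
        strand="+", biotype="protein_coding",
        exons=[(1000, 1200), (2000, 2200)],
    )


@pytest.fixture
def nested_genes():
    """Outer and inner gene on the same strand; inner is shorter."""
    outer = GeneModel(
        gene_id="OUTER", chromosome="chr2", start=1_000, end=100_000,
        strand="+", biotype="protein_coding",
        exons=[(1_000, 1_500), (99_000, 100_000)],
    )
    inner = GeneModel(
        gene_id="INNER", chromosome="chr2", start=10_000, end=30_000,
        strand="+", biotype="protein_coding",
        exons=[(10_000, 10_500), (29_000, 30_000)],
    )
    return [outer, inner]


def make_record(chrom="chr1", start=100, end=200, strand="+", count=10, **kw):
    return CircRecord(
        chrom=chrom, start=start, end=end, strand=strand, read_count=count, **kw
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One default in-memory synthetic dataset shared across tests."""
    return simulate_dataset(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default on-disk bundle (paths dict, truth) shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(SynthConfig(seed=11), out)
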