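import pytest

from isoviz import FixtureConfig, generate, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """In-memory synthetic dataset: (annotation, wide counts, metadata, truth)."""
    return simulate_dataset(FixtureConfig(seed=1))


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The same dataset written to disk (GTF + CSVs + truth JSON)."""
    out = tmp_path_factory.mktemp("fixture")
    return generate(FixtureConfig(seed=1), out)


@pytest.fixture()
def tiny_gtf(tmp_path):
    """Two-line GTF: one exon + one CDS of transcript T1."""
    text = (
        'chr1\ttest\texon\t100\t200\t.\t+\t.\t'
        'gene_id "G1"; gene_name "ALPHA"; transcript_id "T1"; transcript_name "ALPHA-201";\n'
        'chr1\ttest\tCDS\t120\t180\t.\t+\t.\t'
        'gene_id "G1"; gene_name "ALPHA"; transcript_id "T1"; transcript_name "ALPHA-201";\n'
    )
    path = tmp_path / "tiny.gtf"
    path.write_text(text)
    return path
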