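import pytest

from fasmosaic.datasets import fixture_pileup, fixture_report
from fasmosaic.pileup_io import write_pileup_tsv


@pytest.fixture()
def table2_pileup():
    """The 12 bundled report records as stranded allele counts."""
    return fixture_pileup()


@pytest.fixture()
def table2_report():
    return fixture_report()


@pytest.fixture()
def table2_tsv(tmp_path, table2_pileup):
    """The bundled records transcribed to a pileup TSV file."""
    path = tmp_path / "table2.pileup.tsv"
    write_pileup_tsv(table2_pileup, path)
    return path
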