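import pytest

from mitocohort.annotation import MitoGenomeModel
from mitocohort.haplogroups import HaplogroupMarkerTable
from mitocohort.simulate import synthetic_model, synthetic_reference


@pytest.fixture(scope="session")
def gene_model() -> MitoGenomeModel:
    """Packaged gene map, no reference bases."""
    return MitoGenomeModel.default()


@pytest.fixture(scope="session")
def seq_model() -> MitoGenomeModel:
    """Packaged gene map over the synthetic reference sequence."""
    return synthetic_model()


@pytest.fixture(scope="session")
def marker_table() -> HaplogroupMarkerTable:
    return HaplogroupMarkerTable.default()


@pytest.fixture(scope="session")
def reference() -> str:
    return synthetic_reference()
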