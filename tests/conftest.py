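import pytest

from qsoxphylo.motifs import annotate_family
from qsoxphylo.simulate import FamilyConfig, evolve_family

FAMILY_SEED = 7


@pytest.fixture(scope="session")
def family():
    """A default 40-taxon synthetic family with ground truth."""
    return evolve_family(FamilyConfig(seed=FAMILY_SEED))


@pytest.fixture(scope="session")
def family_annotations(family):
    records, _ = family
    anns, fails = annotate_family(records)
    return anns, fails
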