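import pytest

from ohnolog_forge.config import SimulationConfig, ladder_species_tree
from ohnolog_forge.simulate import Family, FamilySet
from ohnolog_forge.trees import parse_newick


@pytest.fixture(scope="session")
def stree():
    """Default vertebrate-style ladder species tree."""
    return ladder_species_tree()


def famset_from_newicks(newicks, gene_species_map, config=None):
    """Hand-built FamilySet (no ground-truth records) for analysis-side tests."""
    families = [Family(f"F{i:04d}", parse_newick(nwk), [], {})
                for i, nwk in enumerate(newicks)]
    return FamilySet(families, dict(gene_species_map), {},
                     config or SimulationConfig())


@pytest.fixture
def hand_famset():
    return famset_from_newicks
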