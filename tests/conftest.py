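import dendropy
import pytest

from wrkyfamkit.io_formats import SequenceRecord
from wrkyfamkit.synthetic_data import FamilyPlantSpec, generate_annotated_genome

# 8-taxon tree used across the branch-site simulations: a long terminal
# branch (A) is the foreground lineage under test
EIGHT_TAXON_NEWICK = (
    "(((A:0.50,B:0.15):0.08,(C:0.15,D:0.15):0.08):0.08,"
    "((E:0.15,F:0.15):0.08,(G:0.15,H:0.15):0.08):0.08);"
)


@pytest.fixture(scope="session")
def default_plant_spec() -> FamilyPlantSpec:
    """Default study conditions for the synthetic genome: every group
    represented, two tandem arrays, two collinear segments."""
    return FamilyPlantSpec(
        n_members={"1": 3, "2a": 3, "2b": 2, "2c": 2, "2d": 2, "2e": 2, "3": 4},
        tandem_clusters=[("Chr1", 3, 2), ("Chr2", 2, 5)],
        segmental_blocks=[(8, 50), (5, 50)],
        background_genes=150,
        n_chromosomes=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def synthetic_genome(default_plant_spec):
    return generate_annotated_genome(default_plant_spec)


@pytest.fixture
def eight_taxon_tree() -> dendropy.Tree:
    return dendropy.Tree.get(data=EIGHT_TAXON_NEWICK, schema="newick")


def make_protein(pid: str, seq: str) -> SequenceRecord:
    return SequenceRecord(pid, seq, "protein")
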