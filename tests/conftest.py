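import pytest

from cobpath.model import FamilyRegistry, GeneFamily, Pathway, load_registry
from cobpath.simulate import SimulationConfig, simulate_reference_set


@pytest.fixture(scope="session")
def registry():
    """The packaged cobalamin-pathway registry with the published count fixture."""
    return load_registry()


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated full-tier database with truth labels (3 families)."""
    config = SimulationConfig(
        seed=11,
        n_families=3,
        members_per_family=3,
        n_decoy_groups=2,
        decoy_members_per_group=2,
        length_range=(120, 160),
        read_length_range=(40, 70),
    )
    db, dataset = simulate_reference_set(config)
    return config, db, dataset


def make_toy_registry(homologs=False):
    """A minimal two-family registry, optionally with declared mutual homology."""
    h = frozenset({"cobA"}), frozenset({"cysG"})
    fams = {
        "cysG": GeneFamily(
            "cysG", "siroheme synthase", frozenset({"precorrin2"}),
            h[0] if homologs else frozenset(),
        ),
        "cobA": GeneFamily(
            "cobA", "uroporphyrinogen-III methyltransferase", frozenset({"precorrin2"}),
            h[1] if homologs else frozenset(),
        ),
    }
    return FamilyRegistry(
        fams, {"precorrin2": Pathway("precorrin2", ("cysG", "cobA"))}
    )


@pytest.fixture
def toy_registry():
    return make_toy_registry(homologs=True)
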