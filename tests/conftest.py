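import numpy as np
import pandas as pd
import pytest

from phylodisp.core_data import Character, CharacterScheme, MorphoMatrix, TaxonomyTable
from phylodisp.simulate import SimConfig, simulate_characters, simulate_tree
from phylodisp.trees import DatedTree


@pytest.fixture(scope="session")
def toy_scheme() -> CharacterScheme:
    """Three characters (2, 3 and 5 states) across two categories."""
    return CharacterScheme(
        [
            Character("B03", "B", "glandular hairs", ("B03-1", "B03-2")),
            Character("B04", "B", "hair branching", ("B04-1", "B04-2", "B04-3")),
            Character("D10", "D", "petal shape", tuple(f"D10-{i}" for i in range(1, 6))),
        ]
    )


@pytest.fixture
def toy_matrix(toy_scheme) -> MorphoMatrix:
    cells = {
        ("Arabis", "B03"): {"B03-1"},
        ("Arabis", "B04"): {"B04-1", "B04-2"},
        ("Arabis", "D10"): {"D10-1"},
        ("Draba", "B03"): {"B03-2"},
        ("Draba", "B04"): {"B04-2"},
        # Draba D10 missing
        ("Lepidium", "B03"): {"B03-1", "B03-2"},
        ("Lepidium", "B04"): {"B04-3"},
        ("Lepidium", "D10"): {"D10-2", "D10-3"},
        ("Orphanus", "B03"): {"B03-1"},
    }
    return MorphoMatrix(toy_scheme, ["Arabis", "Draba", "Lepidium", "Orphanus"], cells)


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(
        genus_to_tribe={
            "Arabis": "Arabideae",
            "Draba": "Arabideae",
            "Lepidium": "Lepidieae",
            "Orphanus": None,
        },
        lineage_schemes={"lineage": {"Arabideae": "I", "Lepidieae": "II"}},
        wgd={"Arabideae": True, "Lepidieae": False},
        rate_shift={"Arabideae": False, "Lepidieae": True},
    )


@pytest.fixture(scope="session")
def small_sim():
    """A 15-tribe synthetic world shared by slower tests."""
    cfg = SimConfig(seed=11, n_tribes=15)
    tree, tax = simulate_tree(cfg)
    matrix = simulate_characters(tree, cfg, tax)
    return cfg, tree, tax, matrix


@pytest.fixture(scope="session")
def balanced_tree() -> DatedTree:
    """Fixed 8-tip ultrametric tree with two deep clades of depth 10."""
    nwk = (
        "(((A:2,B:2):3,(C:4,D:4):1):5,((E:1,F:1):6,(G:3,H:3):4):3);"
    )
    return DatedTree.from_newick(nwk)


def random_morphomatrix(scheme: CharacterScheme, n_genera: int, rng: np.random.Generator,
                        missing: float = 0.1) -> MorphoMatrix:
    """Random polymorphic matrix used by property tests."""
    genera = [f"g{i:03d}" for i in range(n_genera)]
    cells = {}
    for g in genera:
        for char in scheme:
            if rng.random() < missing:
                continue
            size = 1 + rng.binomial(char.k - 1, 0.3)
            states = rng.choice(char.states, size=size, replace=False)
            cells[(g, char.id)] = set(states)
    return MorphoMatrix(scheme, genera, cells)


def random_taxonomy(genera: list[str], n_tribes: int, rng: np.random.Generator,
                    n_lineages: int = 3) -> TaxonomyTable:
    tribes = [f"t{i}" for i in range(n_tribes)]
    assignment = {g: tribes[int(rng.integers(n_tribes))] for g in genera}
    lineages = {t: f"L{int(rng.integers(n_lineages)) + 1}" for t in tribes}
    return TaxonomyTable(genus_to_tribe=assignment, lineage_schemes={"lineage": lineages})
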