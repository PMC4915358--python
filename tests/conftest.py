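import random

import pytest

from paradup import (
    GeneTree,
    SpeciesTree,
    filter_events,
    reconcile_forest,
    validate_forest,
)
from paradup import monocots


@pytest.fixture(scope="session")
def toy_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def toy_gene_species():
    return {"a1": "A", "a2": "A", "a3": "A",
            "b1": "B", "b2": "B", "c1": "C", "c2": "C",
            "x1": "A", "x2": "A", "y1": "B",
            "p1": "A", "p2": "A", "q1": "B"}


@pytest.fixture(scope="session")
def monocot_tree() -> SpeciesTree:
    return monocots.monocot_species_tree()


@pytest.fixture
def rng():
    return random.Random(20160324)


def toy_forest(species_tree, gene_species, newicks):
    """Build a validated forest from orthogroup-id -> newick text."""
    trees = {og: GeneTree.from_newick(text, og) for og, text in newicks.items()}
    orthogroups = {og: frozenset(t.leaf_names) for og, t in trees.items()}
    return validate_forest(orthogroups, trees, gene_species, species_tree)


@pytest.fixture
def filtered_toy_catalog(toy_species_tree, toy_gene_species):
    """Three-orthogroup fixture: one fully retained internal event (OG1),
    one terminal event (OG2), one internal event with a species missing a
    copy (OG3)."""
    forest = toy_forest(toy_species_tree, toy_gene_species, {
        "OG1": "(((a1,b1),(a2,b2)),c1);",   # retained duplication on {A,B}
        "OG2": "((x1,x2),y1);",             # terminal duplication on A
        "OG3": "((p1,q1),p2);",             # {A,B} event, B lost one copy
    })
    return filter_events(reconcile_forest(forest))
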