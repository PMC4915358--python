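"""Packaged example species tree for the monocot analysis.

Seven taxa: the two Andropogoneae C4 species (*Zea mays*, *Sorghum
bicolor*), the two Paniceae C4 species (*Setaria italica*, *Panicum
virgatum*), two C3 grasses of the BOP clade (*Oryza sativa*, *Brachypodium
distachyon*) and a placeholder non-grass outgroup.  The study design names
six monocots explicitly and counts seven; the seventh is represented here
by the ``Outgroup`` placeholder taxon so that the grass crown branch is a
proper internal branch.

Branch lengths are unit lengths (one expected duplication-clock unit per
edge); they only scale the simulator's event rates, not the reconciliation.
"""

from __future__ import annotations

from .parallel import FocalBranchPair
from .trees import SpeciesTree

MONOCOT_NEWICK = (
    "((((Zmays:1,Sbicolor:1):1,(Sitalica:1,Pvirgatum:1):1):1,"
    "(Osativa:1,Bdistachyon:1):2):1,Outgroup:4);"
)

#: branch on which C4 arose in the Andropogoneae
ANDROPOGONEAE = frozenset({"Zmays", "Sbicolor"})
#: branch on which C4 arose in the Paniceae
PANICEAE = frozenset({"Sitalica", "Pvirgatum"})
#: crown Panicoideae branch (ancestor of both C4 clades)
PANICOIDEAE = ANDROPOGONEAE | PANICEAE
#: crown-grass branch: duplications here predate the C4 origins
POACEAE = PANICOIDEAE | {"Osativa", "Bdistachyon"}
#: species used for whole-leaf dominance comparisons
CONCORDANCE_SPECIES = ("Zmays", "Osativa")


def monocot_species_tree() -> SpeciesTree:
    return SpeciesTree.from_newick(MONOCOT_NEWICK)


def c4_focal_pair() -> FocalBranchPair:
    """The two independent C4-origin branches."""
    return FocalBranchPair(ANDROPOGONEAE, PANICEAE)
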