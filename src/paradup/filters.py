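"""Retention filtering of duplication events.

Two criteria decide whether a duplication counts as retained:

1. the event must be witnessed by at least ``min_evidence_species`` species,
   where a species witnesses a duplication only if it retains a gene in
   *both* paralog clades (under the default threshold of 2 every
   terminal-branch event fails);
2. full retention: every species descending from the event's species-tree
   branch must retain at least one gene in each paralog clade.

Criterion 2 implies criterion 1 whenever the event's branch has >= 2
descendant species.  Events mapping to the species-tree root are kept but
flagged, since "species that diverged after the duplication" is then the
whole species set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, List, Optional

import pandas as pd

from .reconcile import DuplicationEvent, EventCatalog
from .trees import SpeciesTree

__all__ = [
    "RetentionCriteria",
    "FilteredCatalog",
    "evidence_species",
    "passes_criterion1",
    "passes_criterion2",
    "filter_events",
    "branch_summary",
    "chain_counts",
]


@dataclass(frozen=True)
class RetentionCriteria:
    """Thresholds of the retention filter."""

    min_evidence_species: int = 2
    require_full_retention: bool = True

    def __post_init__(self) -> None:
        if self.min_evidence_species < 1:
            raise ValueError("min_evidence_species must be >= 1")


def evidence_species(event: DuplicationEvent) -> FrozenSet[str]:
    """Species retaining a gene in both paralog clades of the event."""
    return event.species_a & event.species_b


def passes_criterion1(event: DuplicationEvent,
                      criteria: RetentionCriteria = RetentionCriteria()) -> bool:
    return len(evidence_species(event)) >= criteria.min_evidence_species


def passes_criterion2(event: DuplicationEvent,
                      species_tree: Optional[SpeciesTree] = None) -> bool:
    """Full retention: every descendant species keeps a copy in each clade.

    The descendant species of the event are exactly its branch key, so the
    species tree is only needed by callers that want the branch validated.
    """
    if species_tree is not None and event.branch not in species_tree.branch_to_node:
        raise ValueError(f"event branch {sorted(event.branch)} is not a "
                         "species-tree branch")
    return event.branch <= event.species_a and event.branch <= event.species_b


@dataclass
class FilteredCatalog:
    """Event catalog with retention flags and materialised subsets."""

    catalog: EventCatalog
    criteria: RetentionCriteria
    events: List[DuplicationEvent]

    @property
    def species_tree(self) -> SpeciesTree:
        return self.catalog.species_tree

    @property
    def all_events(self) -> List[DuplicationEvent]:
        return self.events

    @property
    def internal_events(self) -> List[DuplicationEvent]:
        return [e for e in self.events if not e.is_terminal]

    @property
    def criterion1_events(self) -> List[DuplicationEvent]:
        return [e for e in self.events if e.criterion1]

    @property
    def retained_events(self) -> List[DuplicationEvent]:
        if self.criteria.require_full_retention:
            return [e for e in self.events if e.criterion1 and e.criterion2]
        return [e for e in self.events if e.criterion1]

    @property
    def root_events(self) -> List[DuplicationEvent]:
        """Events mapping to the species-tree root branch (kept, flagged)."""
        root_key = self.species_tree.branch_key(self.species_tree.root.index)
        return [e for e in self.events if e.branch == root_key]

    def counts(self) -> Dict[str, int]:
        return {
            "total": len(self.events),
            "terminal": sum(e.is_terminal for e in self.events),
            "nonterminal": sum(not e.is_terminal for e in self.events),
            "criterion1": len(self.criterion1_events),
            "retained": len(self.retained_events),
        }

    def retained_orthogroups(self, branch: Optional[FrozenSet[str]] = None
                             ) -> FrozenSet[str]:
        """Orthogroups with >= 1 retained event (optionally on one branch)."""
        return frozenset(
            e.orthogroup for e in self.retained_events
            if branch is None or e.branch == branch
        )

    def retained_on_branch(self, branch: FrozenSet[str]) -> List[DuplicationEvent]:
        branch = frozenset(branch)
        return [e for e in self.retained_events if e.branch == branch]

    def to_frame(self) -> pd.DataFrame:
        frame = EventCatalog(self.catalog.species_tree, self.events,
                             self.catalog.trees, self.catalog.orthogroups,
                             self.catalog.gene_species).to_frame()
        frame["retained"] = [bool(e.criterion1 and e.criterion2)
                             for e in self.events]
        return frame


def filter_events(catalog: EventCatalog,
                  criteria: RetentionCriteria = RetentionCriteria(),
                  species_tree: Optional[SpeciesTree] = None) -> FilteredCatalog:
    """Apply both retention criteria and materialise the filtered catalog."""
    st = species_tree if species_tree is not None else catalog.species_tree
    flagged = [
        replace(event,
                criterion1=passes_criterion1(event, criteria),
                criterion2=passes_criterion2(event, st))
        for event in catalog.events
    ]
    return FilteredCatalog(catalog, criteria, flagged)


def branch_summary(filtered: FilteredCatalog,
                   species_tree: Optional[SpeciesTree] = None) -> pd.DataFrame:
    """Retained events and orthogroups per nonterminal species-tree branch.

    One row per nonterminal branch (root included, flagged ``is_root``):
    branch key, number of retained events, number of distinct orthogroups
    with >= 1 retained event on the branch.  Event counts sum to the total
    retained count whenever criterion 1 requires >= 2 evidence species.
    """
    st = species_tree if species_tree is not None else filtered.species_tree
    root_key = st.branch_key(st.root.index)
    per_branch_events: Dict[FrozenSet[str], int] = {}
    per_branch_ogs: Dict[FrozenSet[str], set] = {}
    for event in filtered.retained_events:
        per_branch_events[event.branch] = per_branch_events.get(event.branch, 0) + 1
        per_branch_ogs.setdefault(event.branch, set()).add(event.orthogroup)
    rows = []
    for key in sorted(st.internal_branch_keys(), key=lambda k: (len(k), sorted(k))):
        rows.append({
            "branch": ",".join(sorted(key)),
            "n_species": len(key),
            "is_root": key == root_key,
            "n_events": per_branch_events.get(key, 0),
            "n_orthogroups": len(per_branch_ogs.get(key, ())),
        })
    return pd.DataFrame(rows, columns=["branch", "n_species", "is_root",
                                       "n_events", "n_orthogroups"])


def chain_counts(total_events: int, terminal_events: int) -> Dict[str, int]:
    """Bookkeeping of the filter cascade from aggregate counts alone.

    Given a total event count and the number mapping to terminal branches,
    returns the cascade stage sizes, in particular the number of events
    surviving criterion 1 when evidence from >= 2 species is required
    (terminal events cannot be witnessed by two species, so the survivors
    are exactly the nonterminal events).
    """
    if terminal_events > total_events or min(total_events, terminal_events) < 0:
        raise ValueError("terminal_events must lie in [0, total_events]")
    return {
        "total": total_events,
        "terminal": terminal_events,
        "criterion1_survivors": total_events - terminal_events,
    }
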