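"""Parallel duplication detection on two focal species-tree branches.

Retained duplications on the two branches are compared at two levels:

* orthogroup level — the same gene family duplicated on both branches; the
  size of the overlap is tested against the hypergeometric null given the
  orthogroup universe and the per-branch orthogroup counts;
* gene level ("same gene") — the two duplications hit orthologous copies of
  the ancestral gene: every internal node on the gene-tree path between the
  two duplication nodes (their LCA included, the endpoints excluded) is a
  speciation.  If one duplication is an ancestor of the other the pair is
  not parallel by convention.

The hypergeometric tail is evaluated in log space so that p-values far
below double rounding (1e-21 and beyond) keep a meaningful log10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .filters import FilteredCatalog
from .reconcile import DUPLICATION, SPECIATION, DuplicationEvent, ReconciledGeneTree
from .trees import SpeciesTree

__all__ = [
    "FocalBranchPair",
    "OverlapResult",
    "ParallelEvent",
    "hypergeometric_tail",
    "log10_hypergeometric_tail",
    "overlap_enrichment",
    "same_gene_parallel",
    "find_parallel_events",
]


@dataclass(frozen=True)
class FocalBranchPair:
    """Two nonterminal species-tree branches, neither ancestral to the other."""

    branch1: FrozenSet[str]
    branch2: FrozenSet[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "branch1", frozenset(self.branch1))
        object.__setattr__(self, "branch2", frozenset(self.branch2))
        if len(self.branch1) < 2 or len(self.branch2) < 2:
            raise ValueError("focal branches must be nonterminal (>= 2 species)")
        if self.branch1 <= self.branch2 or self.branch2 <= self.branch1:
            raise ValueError("focal branches must not be nested (independence)")

    def validate(self, species_tree: SpeciesTree) -> "FocalBranchPair":
        for key in (self.branch1, self.branch2):
            if key not in species_tree.branch_to_node:
                raise KeyError(f"{sorted(key)} is not a species-tree branch")
        return self


def _log_tail(N: int, K: int, n: int, k: int) -> float:
    """Natural log of P(X >= k), X ~ Hypergeometric(N, K, n)."""
    upper = min(K, n)
    lower = max(0, n + K - N)
    if k > upper:
        return -math.inf
    if k <= lower:
        return 0.0
    support = np.arange(k, upper + 1)
    return float(logsumexp(hypergeom.logpmf(support, N, K, n)))


def _check_counts(N: int, K: int, n: int, k: int) -> None:
    for name, value in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(value) != value or value < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    if K > N or n > N:
        raise ValueError(f"inconsistent counts: K={K}, n={n} must not exceed N={N}")


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail p-value P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed by a log-space sum over the support, so extreme tails keep
    full relative precision before exponentiation.
    """
    _check_counts(N, K, n, k)
    return float(math.exp(_log_tail(N, K, n, k)))


def log10_hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """log10 of the upper-tail p-value (useful when p underflows linear scale)."""
    _check_counts(N, K, n, k)
    return _log_tail(N, K, n, k) / math.log(10.0)


@dataclass
class OverlapResult:
    """Orthogroup-level overlap of retained duplications on two branches."""

    N: int                 # orthogroup universe size
    K: int                 # orthogroups with >= 1 retained event on branch 1
    n: int                 # same for branch 2
    k_obs: int             # orthogroups with events on both branches
    expected: float        # n * K / N
    p_value: float         # upper-tail hypergeometric
    log10_p: float
    branch1: FrozenSet[str] = frozenset()
    branch2: FrozenSet[str] = frozenset()

    def to_dict(self) -> Dict[str, object]:
        return {
            "branch1": ",".join(sorted(self.branch1)),
            "branch2": ",".join(sorted(self.branch2)),
            "N": self.N, "K": self.K, "n": self.n, "k_obs": self.k_obs,
            "expected": self.expected, "p_value": self.p_value,
            "log10_p": self.log10_p,
        }


def default_universe(filtered: FilteredCatalog, pair: FocalBranchPair
                     ) -> FrozenSet[str]:
    """Orthogroups containing >= 1 gene from >= 1 species of each focal clade."""
    catalog = filtered.catalog
    out: Set[str] = set()
    for og, genes in catalog.orthogroups.items():
        species = {catalog.gene_species[g] for g in genes} \
            if catalog.gene_species else set()
        if species & pair.branch1 and species & pair.branch2:
            out.add(og)
    return frozenset(out)


def overlap_enrichment(filtered: FilteredCatalog, pair: FocalBranchPair,
                       universe: Optional[Iterable[str]] = None) -> OverlapResult:
    """Count the orthogroup-level overlap on the focal pair and test it.

    ``universe=None`` uses the default policy (orthogroups with genes from
    both focal clades); ``universe="all"`` uses every orthogroup in the
    catalog; otherwise an explicit orthogroup collection is used and must
    cover all orthogroups with events on either branch.
    """
    pair.validate(filtered.species_tree)
    ogs1 = filtered.retained_orthogroups(pair.branch1)
    ogs2 = filtered.retained_orthogroups(pair.branch2)
    if universe is None:
        uni = default_universe(filtered, pair) | ogs1 | ogs2
    elif isinstance(universe, str) and universe == "all":
        uni = frozenset(filtered.catalog.orthogroups)
    else:
        uni = frozenset(universe)
        stray = (ogs1 | ogs2) - uni
        if stray:
            raise ValueError(
                "universe must cover all orthogroups with focal-branch events; "
                f"missing {sorted(stray)[:5]}..."
            )
    if not uni:
        raise ValueError("orthogroup universe is empty")
    K = len(ogs1 & uni)
    n = len(ogs2 & uni)
    k_obs = len(ogs1 & ogs2 & uni)
    N = len(uni)
    expected = n * K / N
    return OverlapResult(N=N, K=K, n=n, k_obs=k_obs, expected=expected,
                         p_value=hypergeometric_tail(N, K, n, k_obs),
                         log10_p=log10_hypergeometric_tail(N, K, n, k_obs),
                         branch1=pair.branch1, branch2=pair.branch2)


def same_gene_parallel(rtree: ReconciledGeneTree, d1: int, d2: int) -> bool:
    """Were two duplications in one orthogroup hits on the *same* gene?

    True iff every internal node strictly between the two duplication nodes
    on the gene-tree path (their LCA included) is a speciation, i.e. the
    pre-duplication copies are orthologs.  False when either node is an
    ancestor of the other.  Symmetric in (d1, d2).
    """
    labels = rtree.labels
    for d in (d1, d2):
        if not 0 <= d < rtree.gene_tree.n_nodes or labels[d] != DUPLICATION:
            raise ValueError(f"node {d} is not a duplication node of this tree")
    if d1 == d2:
        raise ValueError("same_gene_parallel needs two distinct duplication nodes")
    lca = rtree.gene_lca(d1, d2)
    if lca == d1 or lca == d2:
        return False
    nodes = rtree.gene_tree.nodes
    for start in (d1, d2):
        node = nodes[start].parent
        while node is not None and node.index != lca:
            if labels[node.index] != SPECIATION:
                return False
            node = node.parent
    return labels[lca] == SPECIATION


@dataclass
class ParallelEvent:
    """A pair of retained duplications on the two focal branches."""

    orthogroup: str
    event1: DuplicationEvent
    event2: DuplicationEvent
    level: str                       # "orthogroup" | "gene"
    lineage_node: Optional[int] = None  # gene-tree LCA (ancestral gene lineage)

    def to_dict(self) -> Dict[str, object]:
        return {
            "orthogroup": self.orthogroup,
            "level": self.level,
            "branch1": ",".join(sorted(self.event1.branch)),
            "node1": self.event1.node_index,
            "branch2": ",".join(sorted(self.event2.branch)),
            "node2": self.event2.node_index,
            "lineage_node": self.lineage_node,
        }


def find_parallel_events(filtered: FilteredCatalog, pair: FocalBranchPair
                         ) -> List[ParallelEvent]:
    """Enumerate parallel duplications on the focal branch pair.

    Each orthogroup with retained events on both branches contributes one
    orthogroup-level record (representative pair: smallest node indices).
    Every cross pair of events is tested with :func:`same_gene_parallel`;
    qualifying pairs are recorded at gene level, deduplicated per ancestral
    gene lineage (the gene-tree LCA of the pair), so serial duplications
    within one orthologous lineage count once.
    """
    pair.validate(filtered.species_tree)
    by_og: Dict[str, Tuple[List[DuplicationEvent], List[DuplicationEvent]]] = {}
    for event in filtered.retained_events:
        if event.branch == pair.branch1:
            by_og.setdefault(event.orthogroup, ([], []))[0].append(event)
        elif event.branch == pair.branch2:
            by_og.setdefault(event.orthogroup, ([], []))[1].append(event)
    out: List[ParallelEvent] = []
    for og in sorted(by_og):
        on1, on2 = by_og[og]
        if not on1 or not on2:
            continue
        on1 = sorted(on1, key=lambda e: e.node_index)
        on2 = sorted(on2, key=lambda e: e.node_index)
        out.append(ParallelEvent(og, on1[0], on2[0], "orthogroup"))
        rtree = filtered.catalog.trees[og]
        seen_lineages: Set[int] = set()
        for e1, e2 in product(on1, on2):
            if not same_gene_parallel(rtree, e1.node_index, e2.node_index):
                continue
            lineage = rtree.gene_lca(e1.node_index, e2.node_index)
            if lineage in seen_lineages:
                continue
            seen_lineages.add(lineage)
            out.append(ParallelEvent(og, e1, e2, "gene", lineage))
    return out


def parallel_counts(events: List[ParallelEvent]) -> Dict[str, int]:
    return {
        "orthogroup_level": sum(e.level == "orthogroup" for e in events),
        "gene_level": sum(e.level == "gene" for e in events),
    }
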