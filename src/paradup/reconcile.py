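"""Gene-tree / species-tree reconciliation by duplication-loss parsimony.

Each gene-tree node ``v`` is mapped to the species-tree lowest common
ancestor ``M(v)`` of the species of its descendant genes (the classic LCA
mapping).  An internal node is a duplication iff ``M(v)`` equals the mapping
of at least one of its children, otherwise a speciation.  Losses on the edge
``(v, c)`` count the species-tree edges skipped on the path from ``M(v)``
down to ``M(c)``: ``d(M(v), M(c)) - 1`` below a speciation and
``d(M(v), M(c))`` below a duplication.

The mapping is computed in one postorder traversal with constant-time
species-tree LCA queries (Euler tour preprocessing in
:class:`~paradup.trees.SpeciesTree`), so a forest of thousands of
orthogroups reconciles in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

import numpy as np

from .trees import (
    Forest,
    GeneTree,
    SpeciesTree,
    TreeNode,
    serialize_newick,
)

__all__ = [
    "LEAF",
    "SPECIATION",
    "DUPLICATION",
    "ReconciliationError",
    "DuplicationEvent",
    "ReconciledGeneTree",
    "EventCatalog",
    "lca_map",
    "label_events",
    "count_losses",
    "reconcile_gene_tree",
    "reconcile_forest",
    "root_by_cost",
]

LEAF = 0
SPECIATION = 1
DUPLICATION = 2

_LABEL_CODE = {LEAF: "L", SPECIATION: "S", DUPLICATION: "D"}


class ReconciliationError(ValueError):
    """Raised for inputs that cannot be reconciled (e.g. unmapped genes)."""


@dataclass
class DuplicationEvent:
    """One gene-duplication node of a reconciled gene tree.

    ``branch`` is the species-tree branch the event maps to, addressed by
    the set of species descending from ``M(v)``; ``clade_a`` / ``clade_b``
    are the gene leaf sets of the two children of the duplication node.
    ``criterion1`` / ``criterion2`` are retention-filter flags, unset until
    :func:`paradup.filters.filter_events` runs.
    """

    orthogroup: str
    node_index: int
    branch: FrozenSet[str]
    clade_a: FrozenSet[str]
    clade_b: FrozenSet[str]
    species_a: FrozenSet[str]
    species_b: FrozenSet[str]
    criterion1: Optional[bool] = None
    criterion2: Optional[bool] = None

    @property
    def is_terminal(self) -> bool:
        """True when the event maps to a terminal (single-species) branch."""
        return len(self.branch) == 1

    @property
    def key(self) -> Tuple[str, int]:
        return (self.orthogroup, self.node_index)


@dataclass
class ReconciledGeneTree:
    """Gene tree plus LCA mapping, node labels and duplication events."""

    gene_tree: GeneTree
    species_tree: SpeciesTree
    mapping: np.ndarray          # gene node index -> species node index
    labels: np.ndarray           # gene node index -> LEAF/SPECIATION/DUPLICATION
    events: List[DuplicationEvent]
    orthogroup: str = ""

    def losses(self) -> Tuple[np.ndarray, int]:
        return count_losses(self)

    @property
    def n_duplications(self) -> int:
        return len(self.events)

    def gene_lca(self, i: int, j: int) -> int:
        """Gene-tree LCA of nodes ``i`` and ``j`` (parent-pointer walk)."""
        nodes = self.gene_tree.nodes
        seen = set()
        a: Optional[TreeNode] = nodes[i]
        while a is not None:
            seen.add(a.index)
            a = a.parent
        b: Optional[TreeNode] = nodes[j]
        while b is not None:
            if b.index in seen:
                return b.index
            b = b.parent
        raise ValueError("nodes are not in the same tree")

    def to_annotated_newick(self) -> str:
        """Newick with internal labels ``<D|S>=<sorted branch species>``."""
        tree = self.gene_tree.root.copy()
        copied = list(tree.postorder())
        for node, orig in zip(copied, self.gene_tree.nodes):
            if not node.is_leaf:
                code = _LABEL_CODE[int(self.labels[orig.index])]
                branch = ",".join(sorted(
                    self.species_tree.branch_key(int(self.mapping[orig.index]))))
                node.name = f"{code}={branch}"
        return serialize_newick(tree)


def lca_map(gene_tree: GeneTree, species_tree: SpeciesTree,
            gene_species: Dict[str, str]) -> np.ndarray:
    """LCA mapping of every gene-tree node to a species-tree node index."""
    n = gene_tree.n_nodes
    mapping = np.full(n, -1, dtype=np.int64)
    leaf_index = species_tree.leaf_index
    for node in gene_tree.nodes:  # postorder: children precede parents
        if node.is_leaf:
            try:
                species = gene_species[node.name]
                mapping[node.index] = leaf_index[species]
            except KeyError:
                raise ReconciliationError(
                    f"gene {node.name!r} has no species mapping on the species tree"
                ) from None
        else:
            acc = mapping[node.children[0].index]
            for child in node.children[1:]:
                acc = species_tree.lca(int(acc), int(mapping[child.index]))
            mapping[node.index] = acc
    return mapping


def label_events(gene_tree: GeneTree, species_tree: SpeciesTree,
                 mapping: np.ndarray, orthogroup: str = "",
                 gene_species: Optional[Dict[str, str]] = None,
                 ) -> ReconciledGeneTree:
    """Label every internal node speciation/duplication and emit events.

    A node is a duplication iff its mapping equals the mapping of at least
    one child (invariant under swapping children).  One
    :class:`DuplicationEvent` is emitted per duplication node, assigned to
    the species-tree branch whose lower node is ``M(v)``.
    """
    n = gene_tree.n_nodes
    labels = np.zeros(n, dtype=np.int8)
    leafsets: List[FrozenSet[str]] = [frozenset()] * n
    events: List[DuplicationEvent] = []
    for node in gene_tree.nodes:
        i = node.index
        if node.is_leaf:
            labels[i] = LEAF
            leafsets[i] = frozenset([node.name])
            continue
        leafsets[i] = frozenset().union(*(leafsets[c.index] for c in node.children))
        if any(mapping[i] == mapping[c.index] for c in node.children):
            labels[i] = DUPLICATION
        else:
            labels[i] = SPECIATION
    if gene_species is None:
        gene_species = {}
    for node in gene_tree.nodes:
        i = node.index
        if labels[i] != DUPLICATION:
            continue
        left, right = node.children[0], node.children[1]
        clade_a = leafsets[left.index]
        clade_b = leafsets[right.index]
        species_a = frozenset(gene_species.get(g, g) for g in clade_a) \
            if gene_species else _leaf_species(species_tree, mapping, gene_tree, clade_a)
        species_b = frozenset(gene_species.get(g, g) for g in clade_b) \
            if gene_species else _leaf_species(species_tree, mapping, gene_tree, clade_b)
        events.append(DuplicationEvent(
            orthogroup=orthogroup,
            node_index=i,
            branch=species_tree.branch_key(int(mapping[i])),
            clade_a=clade_a,
            clade_b=clade_b,
            species_a=species_a,
            species_b=species_b,
        ))
    return ReconciledGeneTree(gene_tree, species_tree, mapping, labels, events,
                              orthogroup)


def _leaf_species(species_tree: SpeciesTree, mapping: np.ndarray,
                  gene_tree: GeneTree, genes: FrozenSet[str]) -> FrozenSet[str]:
    by_name = {leaf.name: leaf.index for leaf in gene_tree.leaves}
    return frozenset(
        next(iter(species_tree.branch_key(int(mapping[by_name[g]])))) for g in genes
    )


def count_losses(rtree: ReconciledGeneTree) -> Tuple[np.ndarray, int]:
    """Per-edge loss counts (entry for the edge above each non-root node)."""
    st = rtree.species_tree
    mapping = rtree.mapping
    labels = rtree.labels
    losses = np.zeros(rtree.gene_tree.n_nodes, dtype=np.int64)
    for node in rtree.gene_tree.nodes:
        parent = node.parent
        if parent is None:
            continue
        d = st.edges_between(int(mapping[parent.index]), int(mapping[node.index]))
        if labels[parent.index] == DUPLICATION:
            losses[node.index] = d
        else:
            losses[node.index] = d - 1
    return losses, int(losses.sum())


def reconcile_gene_tree(gene_tree: GeneTree, species_tree: SpeciesTree,
                        gene_species: Dict[str, str],
                        orthogroup: str = "") -> ReconciledGeneTree:
    mapping = lca_map(gene_tree, species_tree, gene_species)
    return label_events(gene_tree, species_tree, mapping, orthogroup, gene_species)


# ---------------------------------------------------------------------------
# parsimony rooting
# ---------------------------------------------------------------------------

def _unrooted_adjacency(root: TreeNode):
    """Collapse a (possibly rooted) tree into an unrooted adjacency map.

    Returns (adjacency dict node_id -> list of (neighbour, length), node
    table id -> TreeNode, edge list of (id_a, id_b)).  A binary root is
    suppressed: its two children become direct neighbours.
    """
    nodes = list(root.postorder())
    adj: Dict[int, List[Tuple[int, Optional[float]]]] = {id(n): [] for n in nodes}
    table: Dict[int, TreeNode] = {id(n): n for n in nodes}

    def connect(a: TreeNode, b: TreeNode, length: Optional[float]) -> None:
        adj[id(a)].append((id(b), length))
        adj[id(b)].append((id(a), length))

    for node in nodes:
        for child in node.children:
            if node is root and len(root.children) == 2:
                continue
            connect(node, child, child.length)
    if len(root.children) == 2:
        a, b = root.children
        la = a.length or 0.0
        lb = b.length or 0.0
        length = la + lb if (a.length is not None or b.length is not None) else None
        connect(a, b, length)
        del adj[id(root)]
        del table[id(root)]
    edges = []
    seen = set()
    for u, neighbours in adj.items():
        for v, _ in neighbours:
            if (v, u) not in seen:
                seen.add((u, v))
                edges.append((u, v))
    return adj, table, edges


def _orient(adj, table, node_id: int, parent_id: Optional[int]) -> TreeNode:
    src = table[node_id]
    out = TreeNode(src.name if src.is_leaf else None)
    for neighbour, length in adj[node_id]:
        if neighbour == parent_id:
            continue
        child = _orient(adj, table, neighbour, node_id)
        child.length = length
        out.add_child(child)
    return out


def root_by_cost(tree: TreeNode | GeneTree, species_tree: SpeciesTree,
                 gene_species: Dict[str, str],
                 weights: Tuple[float, float] = (1.0, 1.0)) -> GeneTree:
    """Root an unrooted gene tree by duplication+loss parsimony.

    Every edge of the unrooted topology is tried as a root position; the
    rooting minimising ``w_dup * duplications + w_loss * losses`` wins.
    Ties break on fewer duplications, then on the lexicographically smallest
    sorted leaf-label tuple of the clade below the root edge (whose first
    element is that clade's smallest leaf label); the winning clade is
    placed as the left child of the new root.
    """
    root = tree.root if isinstance(tree, GeneTree) else tree
    n_leaves = len(root.leaves())
    if n_leaves < 3:
        raise ReconciliationError("root_by_cost requires at least 3 leaves")
    w_dup, w_loss = weights
    adj, table, edges = _unrooted_adjacency(root)

    best = None
    for u, v in edges:
        new_root = TreeNode()
        left = _orient(adj, table, v, u)
        right = _orient(adj, table, u, v)
        new_root.add_child(left)
        new_root.add_child(right)
        candidate = GeneTree(new_root)
        rec = reconcile_gene_tree(candidate, species_tree, gene_species)
        _, n_losses = rec.losses()
        n_dups = rec.n_duplications
        cost = w_dup * n_dups + w_loss * n_losses
        clade = tuple(sorted(left.leaf_names()))
        key = (cost, n_dups, clade)
        if best is None or key < best[0]:
            best = (key, candidate)
    assert best is not None
    winner = best[1]
    # orient left = the tie-break clade (already first child by construction)
    return winner


# ---------------------------------------------------------------------------
# forest-level catalog
# ---------------------------------------------------------------------------

@dataclass
class EventCatalog:
    """All duplication events of a reconciled forest.

    ``orthogroups`` covers every orthogroup of the forest (including
    single-gene orthogroups without trees), which downstream enrichment
    tests use as the default universe.
    """

    species_tree: SpeciesTree
    events: List[DuplicationEvent]
    trees: Dict[str, ReconciledGeneTree]
    orthogroups: Dict[str, FrozenSet[str]]
    gene_species: Dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def branch_counts(self) -> Dict[FrozenSet[str], int]:
        counts: Dict[FrozenSet[str], int] = {}
        for event in self.events:
            counts[event.branch] = counts.get(event.branch, 0) + 1
        return counts

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.events:
            rows.append({
                "orthogroup": e.orthogroup,
                "node_index": e.node_index,
                "branch": ",".join(sorted(e.branch)),
                "n_species_branch": len(e.branch),
                "clade_a": ",".join(sorted(e.clade_a)),
                "clade_b": ",".join(sorted(e.clade_b)),
                "criterion1": e.criterion1,
                "criterion2": e.criterion2,
            })
        columns = ["orthogroup", "node_index", "branch", "n_species_branch",
                   "clade_a", "clade_b", "criterion1", "criterion2"]
        return pd.DataFrame(rows, columns=columns)


def reconcile_forest(forest: Forest) -> EventCatalog:
    """Reconcile every gene tree of a validated forest.

    Orthogroups are processed in sorted order; events inherit the
    orthogroup identifier.  Single-gene orthogroups contribute no events
    but stay in the catalog's orthogroup universe.
    """
    events: List[DuplicationEvent] = []
    trees: Dict[str, ReconciledGeneTree] = {}
    for og in sorted(forest.orthogroups):
        tree = forest.trees.get(og)
        if tree is None:
            continue
        rec = reconcile_gene_tree(tree, forest.species_tree, forest.gene_species, og)
        trees[og] = rec
        events.extend(rec.events)
    return EventCatalog(forest.species_tree, events, trees,
                        dict(forest.orthogroups), dict(forest.gene_species))
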