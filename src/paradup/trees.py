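"""Tree and table input/output.

Rooted trees are held in a light-weight :class:`TreeNode` structure.  Newick
text is parsed with :mod:`dendropy` and converted; serialization is a small
deterministic writer (single-quote quoting of labels containing newick
metacharacters).  Species trees get index structures (postorder numbering,
Euler-tour LCA) used by the reconciliation algorithms.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Union

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "NewickParseError",
    "ForestValidationError",
    "GeneSpeciesMapError",
    "SpeciesTree",
    "GeneTree",
    "Forest",
    "parse_newick",
    "serialize_newick",
    "resolve_polytomies",
    "load_gene_species_map",
    "load_orthogroup_table",
    "validate_forest",
]


class NewickParseError(ValueError):
    """Raised when newick text cannot be parsed into a valid tree."""


class GeneSpeciesMapError(ValueError):
    """Raised for inconsistent or unresolvable gene-to-species maps."""


class ForestValidationError(ValueError):
    """Raised when the gene forest is inconsistent with its tables."""


class TreeNode:
    """A node of a rooted tree.

    Attributes
    ----------
    name : str or None
        Leaf label (or internal label, kept but ignored by the analyses).
    length : float or None
        Length of the edge above this node.
    children : list of TreeNode
    parent : TreeNode or None
    index : int
        Postorder index, assigned when the node is registered in a
        :class:`SpeciesTree` or :class:`GeneTree`; -1 before that.
    """

    __slots__ = ("name", "length", "children", "parent", "index")

    def __init__(self, name: Optional[str] = None, length: Optional[float] = None,
                 children: Optional[Iterable["TreeNode"]] = None):
        self.name = name
        self.length = length
        self.children: List[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.index = -1
        if children is not None:
            for child in children:
                self.add_child(child)

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> List["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    def copy(self) -> "TreeNode":
        """Deep copy of the subtree rooted here (parent link dropped)."""
        mapping: Dict[int, TreeNode] = {}
        for node in self.postorder():
            dup = TreeNode(node.name, node.length)
            dup.children = [mapping[id(c)] for c in node.children]
            for c in dup.children:
                c.parent = dup
            mapping[id(node)] = dup
        return mapping[id(self)]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name!r} {kind}>"


# ---------------------------------------------------------------------------
# newick I/O
# ---------------------------------------------------------------------------

_QUOTE_NEEDED = re.compile(r"[\s():;,\[\]']")


def parse_newick(text: str) -> TreeNode:
    """Parse a single newick statement into a :class:`TreeNode` tree.

    Leaf labels and branch lengths are preserved; internal-node labels are
    kept on the node but ignored by downstream analyses.  Raises
    :class:`NewickParseError` for malformed input (the dendropy message,
    which names the offending position, is propagated) and for duplicate
    leaf labels.
    """
    if text is None or not text.strip():
        raise NewickParseError("empty newick string (offset 0)")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"newick parse error: {exc}") from exc
    if dtree.seed_node is None:  # pragma: no cover - defensive
        raise NewickParseError("newick parse error: no tree found")

    converted: Dict[int, TreeNode] = {}
    for dnode in dtree.postorder_node_iter():
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label is not None:
            label = dnode.label
        node = TreeNode(label, dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(converted[id(dchild)])
        converted[id(dnode)] = node
    root = converted[id(dtree.seed_node)]

    seen: Dict[str, int] = {}
    for leaf in root.leaves():
        if leaf.name is None:
            raise NewickParseError("leaf without a label")
        seen[leaf.name] = seen.get(leaf.name, 0) + 1
    dups = sorted(name for name, k in seen.items() if k > 1)
    if dups:
        raise NewickParseError(f"duplicate leaf labels: {', '.join(dups)}")
    return root


def _format_label(label: str) -> str:
    if _QUOTE_NEEDED.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(length: float) -> str:
    if isinstance(length, float) and length.is_integer() and abs(length) < 1e15:
        return str(int(length))
    return repr(float(length))


def serialize_newick(root: TreeNode) -> str:
    """Write a tree as a newick statement.

    The output round-trips through :func:`parse_newick` with identical
    topology, labels and lengths.  Labels containing newick metacharacters
    are single-quoted.
    """
    parts: List[str] = []

    def fmt(node: TreeNode) -> str:
        if node.children:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                body += _format_label(node.name)
        else:
            body = _format_label(node.name if node.name is not None else "")
        if node.length is not None:
            body += ":" + _format_length(node.length)
        return body

    parts.append(fmt(root))
    return "".join(parts) + ";"


def resolve_polytomies(root: TreeNode) -> TreeNode:
    """Resolve multifurcations deterministically (left-to-right).

    A node with children ``[c1, c2, c3, ...]`` becomes ``((c1, c2), c3, ...)``
    applied repeatedly, so the leftmost pair is nested first.  New internal
    nodes carry no label and zero-length edges.  Mutates and returns the tree.
    """
    for node in list(root.postorder()):
        while len(node.children) > 2:
            left, right = node.children[0], node.children[1]
            joined = TreeNode(None, 0.0)
            joined.children = [left, right]
            left.parent = joined
            right.parent = joined
            joined.parent = node
            node.children = [joined] + node.children[2:]
    return root


# ---------------------------------------------------------------------------
# indexed trees
# ---------------------------------------------------------------------------

class _IndexedTree:
    """Shared postorder indexing for species and gene trees."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: List[TreeNode] = list(root.postorder())
        for i, node in enumerate(self.nodes):
            node.index = i
        self.n_nodes = len(self.nodes)
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        for node in self.nodes:
            for child in node.children:
                self.parent[child.index] = node.index
        self.depth = np.zeros(self.n_nodes, dtype=np.int64)
        for node in root.preorder():
            if node.parent is not None:
                self.depth[node.index] = self.depth[node.parent.index] + 1
        self.leaves: List[TreeNode] = [n for n in self.nodes if n.is_leaf]
        self.leaf_names: List[str] = [n.name for n in self.leaves]

    def __len__(self) -> int:
        return self.n_nodes


class SpeciesTree(_IndexedTree):
    """Rooted binary species tree with constant-time LCA queries.

    Every branch is addressed by the frozenset of species descending from its
    lower node ("branch key"); the branch above the root is addressed by the
    full species set.  LCA queries use an Euler tour with a sparse-table
    range-minimum structure (O(n log n) preprocessing, O(1) per query).
    """

    def __init__(self, root: TreeNode):
        super().__init__(root)
        for node in self.nodes:
            if node.children and len(node.children) != 2 and len(self.leaves) > 1:
                raise ForestValidationError(
                    f"species tree must be strictly binary; node {node.name!r} "
                    f"has {len(node.children)} children"
                )
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ForestValidationError("species tree leaf labels are not unique")
        self.leaf_index: Dict[str, int] = {n.name: n.index for n in self.leaves}
        # descendant species sets, bottom-up
        clades: List[FrozenSet[str]] = [frozenset()] * self.n_nodes
        for node in self.nodes:  # postorder: children first
            if node.is_leaf:
                clades[node.index] = frozenset([node.name])
            else:
                acc: FrozenSet[str] = frozenset()
                for child in node.children:
                    acc = acc | clades[child.index]
                clades[node.index] = acc
        self.clades = clades
        self.branch_to_node: Dict[FrozenSet[str], int] = {
            clade: i for i, clade in enumerate(clades)
        }
        self._build_euler()

    # -- LCA machinery ------------------------------------------------------
    def _build_euler(self) -> None:
        euler: List[int] = []
        first = np.full(self.n_nodes, -1, dtype=np.int64)

        stack = [(self.root, iter(self.root.children))]
        euler.append(self.root.index)
        first[self.root.index] = 0
        while stack:
            node, children = stack[-1]
            child = next(children, None)
            if child is None:
                stack.pop()
                if stack:
                    euler.append(stack[-1][0].index)
            else:
                euler.append(child.index)
                if first[child.index] < 0:
                    first[child.index] = len(euler) - 1
                stack.append((child, iter(child.children)))
        self._euler = np.asarray(euler, dtype=np.int64)
        self._first = first
        depths = self.depth[self._euler]
        m = len(euler)
        levels = max(1, m.bit_length())
        table = np.empty((levels, m), dtype=np.int64)
        table[0] = np.arange(m)
        half = 1  # window size of the previous level
        for level in range(1, levels):
            prev = table[level - 1]
            table[level] = prev
            width = m - 2 * half + 1
            if width > 0:
                a = prev[:width]
                b = prev[half:half + width]
                table[level, :width] = np.where(depths[a] <= depths[b], a, b)
            half *= 2
        self._sparse = table
        self._euler_depth = depths

    def lca(self, i: int, j: int) -> int:
        """Index of the lowest common ancestor of nodes ``i`` and ``j``."""
        if i == j:
            return i
        a, b = int(self._first[i]), int(self._first[j])
        if a > b:
            a, b = b, a
        length = b - a + 1
        level = length.bit_length() - 1
        span = 1 << level
        x = self._sparse[level, a]
        y = self._sparse[level, b - span + 1]
        pos = x if self._euler_depth[x] <= self._euler_depth[y] else y
        return int(self._euler[pos])

    def is_ancestor(self, anc: int, desc: int) -> bool:
        return self.lca(anc, desc) == anc

    def edges_between(self, anc: int, desc: int) -> int:
        """Number of species-tree edges on the path from ``anc`` down to ``desc``."""
        if not self.is_ancestor(anc, desc):
            raise ValueError("edges_between requires anc to be an ancestor of desc")
        return int(self.depth[desc] - self.depth[anc])

    # -- branch addressing --------------------------------------------------
    def branch_key(self, i: int) -> FrozenSet[str]:
        return self.clades[i]

    def node_for_branch(self, key: Iterable[str]) -> int:
        key = frozenset(key)
        try:
            return self.branch_to_node[key]
        except KeyError:
            raise KeyError(
                f"no species-tree branch has descendant set {sorted(key)}"
            ) from None

    def mrca_of_species(self, species: Iterable[str]) -> int:
        idx = None
        for name in species:
            leaf = self.leaf_index[name]
            idx = leaf if idx is None else self.lca(idx, leaf)
        if idx is None:
            raise ValueError("mrca_of_species needs at least one species")
        return idx

    def is_terminal_branch(self, key: FrozenSet[str]) -> bool:
        return len(key) == 1

    def internal_branch_keys(self) -> List[FrozenSet[str]]:
        """Branch keys of all nonterminal branches (internal nodes, root included)."""
        return [self.clades[n.index] for n in self.nodes if not n.is_leaf]

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(parse_newick(text))

    def to_newick(self) -> str:
        return serialize_newick(self.root)


class GeneTree(_IndexedTree):
    """Rooted gene tree over gene identifiers (unique within an orthogroup)."""

    def __init__(self, root: TreeNode, name: Optional[str] = None):
        super().__init__(root)
        self.name = name
        if len(set(self.leaf_names)) != len(self.leaf_names):
            raise ForestValidationError(
                f"gene tree {name!r} has duplicate gene identifiers"
            )

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.nodes if n.children)

    def reindex(self) -> "GeneTree":
        return GeneTree(self.root, self.name)

    @classmethod
    def from_newick(cls, text: str, name: Optional[str] = None) -> "GeneTree":
        return cls(parse_newick(text), name)

    def to_newick(self) -> str:
        return serialize_newick(self.root)


# ---------------------------------------------------------------------------
# tabular inputs
# ---------------------------------------------------------------------------

def _read_tsv(source: Union[str, io.IOBase], names: List[str]) -> pd.DataFrame:
    frame = pd.read_csv(source, sep="\t", comment="#", header=None,
                        names=names, dtype=str, skip_blank_lines=True)
    # tolerate an optional header row repeating the column names
    if len(frame) and list(frame.iloc[0]) == names:
        frame = frame.iloc[1:].reset_index(drop=True)
    return frame


def load_gene_species_map(source: Union[str, io.IOBase],
                          species_tree: Optional[SpeciesTree] = None,
                          ) -> Dict[str, str]:
    """Load a two-column gene_id / species_id TSV into a dict.

    Duplicate gene rows are allowed only if they agree; species must be
    leaves of ``species_tree`` when one is supplied.
    """
    frame = _read_tsv(source, ["gene_id", "species_id"])
    mapping: Dict[str, str] = {}
    for gene, species in frame.itertuples(index=False):
        if gene in mapping and mapping[gene] != species:
            raise GeneSpeciesMapError(
                f"gene {gene!r} mapped to both {mapping[gene]!r} and {species!r}"
            )
        mapping[gene] = species
    if species_tree is not None:
        known = set(species_tree.leaf_names)
        offenders = sorted({s for s in mapping.values() if s not in known})
        if offenders:
            raise GeneSpeciesMapError(
                "species not present in the species tree: " + ", ".join(offenders)
            )
    return mapping


def load_orthogroup_table(source: Union[str, io.IOBase]) -> Dict[str, FrozenSet[str]]:
    """Load a long-format orthogroup table (orthogroup_id \\t gene_id).

    Returns orthogroup -> frozenset of gene ids; gene sets must be pairwise
    disjoint and non-empty.
    """
    frame = _read_tsv(source, ["orthogroup_id", "gene_id"])
    table: Dict[str, set] = {}
    owner: Dict[str, str] = {}
    for og, gene in frame.itertuples(index=False):
        if gene in owner and owner[gene] != og:
            raise ForestValidationError(
                f"gene {gene!r} assigned to orthogroups {owner[gene]!r} and {og!r}"
            )
        owner[gene] = og
        table.setdefault(og, set()).add(gene)
    if not table:
        raise ForestValidationError("orthogroup table is empty")
    return {og: frozenset(genes) for og, genes in table.items()}


@dataclass
class Forest:
    """A validated gene forest: trees, tables and the species tree."""

    species_tree: SpeciesTree
    orthogroups: Dict[str, FrozenSet[str]]
    trees: Dict[str, GeneTree]
    gene_species: Dict[str, str]
    polytomies_resolved: List[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.orthogroups.values())

    def orthogroup_species(self, og: str) -> FrozenSet[str]:
        return frozenset(self.gene_species[g] for g in self.orthogroups[og])


def validate_forest(orthogroups: Dict[str, FrozenSet[str]],
                    trees: Dict[str, GeneTree],
                    gene_species: Dict[str, str],
                    species_tree: SpeciesTree,
                    polytomy_policy: str = "reject") -> Forest:
    """Check a gene forest against its tables and the species tree.

    Every orthogroup with >= 2 genes must have a gene tree whose leaf set
    equals its gene set; every gene must map to a species-tree leaf.
    Multifurcating gene trees are rejected under ``polytomy_policy="reject"``
    (the default) or resolved deterministically left-to-right under
    ``"resolve"`` (resolved orthogroups are listed in the result).
    Idempotent: validating a validated forest is a no-op.
    """
    if polytomy_policy not in ("reject", "resolve"):
        raise ValueError(f"unknown polytomy policy {polytomy_policy!r}")
    known_species = set(species_tree.leaf_names)
    owner: Dict[str, str] = {}
    for og in sorted(orthogroups):
        for gene in orthogroups[og]:
            if gene in owner:
                raise ForestValidationError(
                    f"gene {gene!r} appears in orthogroups {owner[gene]!r} "
                    f"and {og!r} (gene sets must be disjoint)"
                )
            owner[gene] = og
    resolved: List[str] = []
    out_trees: Dict[str, GeneTree] = {}
    for og in sorted(orthogroups):
        genes = orthogroups[og]
        if not genes:
            raise ForestValidationError(f"orthogroup {og!r} is empty")
        for gene in genes:
            if gene not in gene_species:
                raise ForestValidationError(
                    f"gene {gene!r} in orthogroup {og!r} has no species mapping"
                )
            if gene_species[gene] not in known_species:
                raise ForestValidationError(
                    f"gene {gene!r} maps to unknown species {gene_species[gene]!r}"
                )
        if len(genes) < 2:
            continue
        if og not in trees:
            raise ForestValidationError(
                f"orthogroup {og!r} has {len(genes)} genes but no gene tree"
            )
        tree = trees[og]
        leafset = frozenset(tree.leaf_names)
        if leafset != genes:
            missing = sorted(genes - leafset)
            extra = sorted(leafset - genes)
            detail = []
            if missing:
                detail.append("missing from tree: " + ", ".join(missing))
            if extra:
                detail.append("not in orthogroup: " + ", ".join(extra))
            raise ForestValidationError(
                f"orthogroup {og!r} leaf-set mismatch ({'; '.join(detail)})"
            )
        if not tree.is_binary():
            if polytomy_policy == "reject":
                raise ForestValidationError(
                    f"gene tree for orthogroup {og!r} is multifurcating "
                    "(polytomy policy is 'reject')"
                )
            tree = GeneTree(resolve_polytomies(tree.root.copy()), og)
            resolved.append(og)
        out_trees[og] = tree
    return Forest(species_tree, dict(orthogroups), out_trees, dict(gene_species),
                  resolved)
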