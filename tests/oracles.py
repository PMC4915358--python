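"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's fast paths: species LCA
by ancestor-chain intersection, node mapping by folding over descendant
leaves, hypergeometric tails by enumerating draws, BH by the literal
step-up formula.
"""

from __future__ import annotations

import random
from itertools import combinations
from typing import Dict, List

import numpy as np

from paradup.trees import GeneTree, SpeciesTree, TreeNode


def random_topology(labels: List[str], rng: random.Random) -> TreeNode:
    """Uniform-ish random rooted binary tree by sequential random joins."""
    nodes = [TreeNode(label) for label in labels]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        parent = TreeNode()
        parent.add_child(a)
        parent.add_child(b)
        nodes.append(parent)
    return nodes[0]


def random_gene_tree(species_tree: SpeciesTree, n_genes: int,
                     rng: random.Random):
    """Random gene tree with leaves assigned to random species."""
    species = list(species_tree.leaf_names)
    genes = [f"g{i}" for i in range(n_genes)]
    mapping = {g: rng.choice(species) for g in genes}
    return GeneTree(random_topology(genes, rng)), mapping


def naive_species_lca(species_tree: SpeciesTree, names: List[str]) -> int:
    """LCA of species leaves by intersecting ancestor chains (no Euler tour)."""
    def ancestors(name: str) -> List[int]:
        node = species_tree.leaves[
            [leaf.name for leaf in species_tree.leaves].index(name)]
        chain = []
        while node is not None:
            chain.append(node.index)
            node = node.parent
        return chain

    chains = [ancestors(n) for n in names]
    common = set(chains[0])
    for chain in chains[1:]:
        common &= set(chain)
    # deepest common ancestor = first element of any chain that is common
    for idx in chains[0]:
        if idx in common:
            return idx
    raise AssertionError("no common ancestor")  # pragma: no cover


def brute_lca_map(gene_tree: GeneTree, species_tree: SpeciesTree,
                  gene_species: Dict[str, str]) -> np.ndarray:
    """Quadratic mapper: every node from scratch over its descendant leaves."""
    mapping = np.full(gene_tree.n_nodes, -1, dtype=np.int64)
    for node in gene_tree.nodes:
        names = [gene_species[leaf.name] for leaf in
                 ([node] if node.is_leaf else node.leaves())]
        mapping[node.index] = naive_species_lca(species_tree, names)
    return mapping


def brute_duplication_count(gene_tree: GeneTree, species_tree: SpeciesTree,
                            gene_species: Dict[str, str]) -> int:
    mapping = brute_lca_map(gene_tree, species_tree, gene_species)
    count = 0
    for node in gene_tree.nodes:
        if node.is_leaf:
            continue
        if any(mapping[node.index] == mapping[c.index] for c in node.children):
            count += 1
    return count


def brute_loss_count(gene_tree: GeneTree, species_tree: SpeciesTree,
                     gene_species: Dict[str, str]) -> int:
    mapping = brute_lca_map(gene_tree, species_tree, gene_species)

    def depth(idx: int) -> int:
        node = species_tree.nodes[idx]
        d = 0
        while node.parent is not None:
            node = node.parent
            d += 1
        return d

    total = 0
    for node in gene_tree.nodes:
        if node.is_leaf:
            continue
        is_dup = any(mapping[node.index] == mapping[c.index]
                     for c in node.children)
        for child in node.children:
            d = depth(int(mapping[child.index])) - depth(int(mapping[node.index]))
            total += d if is_dup else d - 1
    return total


def enumerate_rootings(root: TreeNode):
    """All rooted versions of an unrooted topology, one per edge."""
    # reuse the package's adjacency splitter but score independently
    from paradup.reconcile import _orient, _unrooted_adjacency

    adj, table, edges = _unrooted_adjacency(root)
    for u, v in edges:
        new_root = TreeNode()
        new_root.add_child(_orient(adj, table, v, u))
        new_root.add_child(_orient(adj, table, u, v))
        yield GeneTree(new_root)


def exhaustive_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws."""
    successes = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return hits / total if total else 1.0


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted
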