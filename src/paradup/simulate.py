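"""Synthetic gene forests and expression tables with planted ground truth.

Gene families evolve by a birth-death process along the species tree: a
single ancestral gene enters at the root, every extant copy duplicates at
rate ``lambda`` and dies at rate ``mu`` (exponential waiting times, rates
per unit branch length), and copies bifurcate at speciations.  Only
surviving lineages are emitted; the planted truth lists every duplication
with surviving descendants of *both* copies, together with its species
branch.  With ``mu = 0`` LCA reconciliation recovers the truth exactly
(count, branch and clade composition), which the test suite exploits.

Parallel duplications on a focal branch pair are planted by construction
(forced events), either in the same ancestral gene lineage (gene level) or
in the two copies of an older duplication on the ancestral branch
(orthogroup level), so truth counts are exact.

Expression tables are simulated at TPM level: log-normal baselines, a
configurable fraction of BS-preferential genes with a fold-change shift,
and — for duplications on a chosen ancestral branch — dominance of one
paralog clade assigned concordantly across two species with probability
``c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import monocots
from .expression import ExpressionTable
from .parallel import FocalBranchPair
from .trees import Forest, GeneTree, SpeciesTree, TreeNode, serialize_newick

__all__ = [
    "SimulationError",
    "ExpressionConfig",
    "PlantedParallel",
    "SimulationConfig",
    "TrueEvent",
    "PlantedTruth",
    "simulate_gene_tree",
    "simulate_forest",
    "simulate_expression",
    "write_forest",
    "write_expression",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantedParallel:
    """Forced parallel duplications on a focal branch pair."""

    pair: FocalBranchPair
    count: int = 0
    level: str = "gene"  # "gene" | "orthogroup"

    def __post_init__(self) -> None:
        if self.level not in ("gene", "orthogroup"):
            raise ValueError("level must be 'gene' or 'orthogroup'")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class ExpressionConfig:
    """Planted structure of the simulated expression tables.

    Defaults describe a C4-leaf-like experiment: three BS and three M
    replicates plus three whole-leaf replicates per species, ~20% of genes
    BS-preferential at 4-fold, log2-scale replicate noise of 0.25 and a
    dominance-concordance rate of 0.74 between the two comparison species.
    """

    bs_fraction: float = 0.2
    fold_change: float = 4.0
    noise_sigma: float = 0.25
    concordance: float = 0.74
    tpm_scale: float = 20.0
    gene_sigma: float = 1.5
    n_replicates: int = 3
    dominant_tpm: float = 100.0
    recessive_tpm: float = 20.0
    leaf_condition: str = "leaf"

    def __post_init__(self) -> None:
        if not 0 <= self.bs_fraction <= 1:
            raise ValueError("bs_fraction must lie in [0, 1]")
        if not 0 <= self.concordance <= 1:
            raise ValueError("concordance must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class SimulationConfig:
    """Full configuration of a synthetic study."""

    species_tree: Optional[SpeciesTree] = None   # default: monocot example tree
    n_orthogroups: int = 100
    duplication_rate: float = 0.08   # events per copy per unit branch length
    loss_rate: float = 0.04
    seed: int = 0
    planted_parallel: Optional[PlantedParallel] = None
    planted_cohort: Optional[Tuple[FrozenSet[str], int]] = None  # (branch, count)
    keep_empty: bool = False
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    concordance_branch: Optional[FrozenSet[str]] = None   # default: crown grasses
    concordance_species: Tuple[str, str] = monocots.CONCORDANCE_SPECIES

    def __post_init__(self) -> None:
        if self.duplication_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_orthogroups < 1:
            raise ValueError("n_orthogroups must be >= 1")
        planted = 0
        if self.planted_parallel is not None:
            planted += self.planted_parallel.count
        if self.planted_cohort is not None:
            planted += self.planted_cohort[1]
        if planted > self.n_orthogroups:
            raise ValueError("planted orthogroups exceed n_orthogroups")

    def tree(self) -> SpeciesTree:
        return self.species_tree if self.species_tree is not None \
            else monocots.monocot_species_tree()


@dataclass
class TrueEvent:
    """A planted duplication: species branch plus the two descendant clades."""

    orthogroup: str
    branch: FrozenSet[str]
    clade_a: FrozenSet[str]
    clade_b: FrozenSet[str]
    planted: Optional[str] = None   # "parallel-gene" | "parallel-orthogroup" |
                                    # "cohort" | None (background birth-death)

    @property
    def signature(self) -> Tuple[str, FrozenSet[str], FrozenSet[str], FrozenSet[str]]:
        a, b = sorted((self.clade_a, self.clade_b), key=sorted)
        return (self.orthogroup, self.branch, a, b)


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a simulated forest."""

    events: List[TrueEvent] = field(default_factory=list)
    bs_genes: Set[str] = field(default_factory=set)
    dominance: Dict[Tuple[str, FrozenSet[str], FrozenSet[str], FrozenSet[str]],
                    Tuple[str, str]] = field(default_factory=dict)

    def events_on(self, branch: FrozenSet[str]) -> List[TrueEvent]:
        branch = frozenset(branch)
        return [e for e in self.events if e.branch == branch]

    def signatures(self) -> Set[Tuple]:
        return {e.signature for e in self.events}


# ---------------------------------------------------------------------------
# birth-death gene-tree simulation
# ---------------------------------------------------------------------------

def _edge_length(node: TreeNode) -> float:
    return node.length if node.length is not None else 1.0


def simulate_gene_tree(species_tree: SpeciesTree, duplication_rate: float,
                       loss_rate: float, rng: np.random.Generator,
                       ) -> Tuple[Optional[TreeNode], List[Tuple[TreeNode, FrozenSet[str]]]]:
    """One birth-death gene tree along the species tree.

    Returns the (pruned) gene-tree root — or None if all lineages died —
    and the truth list of (duplication node, species branch key) for
    duplications with survivors on both sides.  Unary passthrough nodes are
    suppressed during construction; gene leaves carry the species name in
    ``name`` (final identifiers are assigned by :func:`simulate_forest`).
    """
    lam, mu = duplication_rate, loss_rate
    total = lam + mu
    truth: List[Tuple[TreeNode, FrozenSet[str]]] = []

    def along_edge(s_node: TreeNode, remaining: float) -> Optional[TreeNode]:
        # one gene lineage travelling down the edge that ends at s_node
        while True:
            wait = rng.exponential(1.0 / total) if total > 0 else math.inf
            if wait >= remaining:
                return at_node(s_node)
            remaining -= wait
            if rng.random() < lam / total:
                left = along_edge(s_node, remaining)
                right = along_edge(s_node, remaining)
                if left is not None and right is not None:
                    dup = TreeNode()
                    dup.add_child(left)
                    dup.add_child(right)
                    truth.append((dup, species_tree.branch_key(s_node.index)))
                    return dup
                return left if left is not None else right
            return None  # loss

    def at_node(s_node: TreeNode) -> Optional[TreeNode]:
        if s_node.is_leaf:
            return TreeNode(s_node.name)
        children = [along_edge(c, _edge_length(c)) for c in s_node.children]
        alive = [c for c in children if c is not None]
        if not alive:
            return None
        if len(alive) == 1:
            return alive[0]
        node = TreeNode()
        for c in alive:
            node.add_child(c)
        return node

    root = at_node(species_tree.root)
    if root is not None and root.is_leaf is False and len(root.children) == 1:
        root = root.children[0]  # cannot happen after suppression, defensive
    # drop truth entries whose node was suppressed out of the surviving tree
    if root is None:
        return None, []
    kept = {id(n) for n in root.postorder()}
    truth = [(node, branch) for node, branch in truth if id(node) in kept]
    return root, truth


# ---------------------------------------------------------------------------
# forced (planted) trees
# ---------------------------------------------------------------------------

def _forced_tree(species_tree: SpeciesTree,
                 plan: Dict[FrozenSet[str], Tuple[Dict, Dict]],
                 ) -> Tuple[TreeNode, List[Tuple[TreeNode, FrozenSet[str]]]]:
    """Deterministic gene tree with duplications forced on chosen branches.

    ``plan`` maps a branch key to the pair of sub-plans carried on by the
    two copies created there; duplications happen at most once per planned
    edge, everything else is congruent with the species tree.
    """
    truth: List[Tuple[TreeNode, FrozenSet[str]]] = []

    def on_edge(s_node: TreeNode, events: Dict) -> TreeNode:
        key = species_tree.branch_key(s_node.index)
        if key in events:
            ev_left, ev_right = events[key]
            rest = {k: v for k, v in events.items() if k != key}
            dup = TreeNode()
            dup.add_child(at_node(s_node, {**rest, **ev_left}))
            dup.add_child(at_node(s_node, {**rest, **ev_right}))
            truth.append((dup, key))
            return dup
        return at_node(s_node, events)

    def at_node(s_node: TreeNode, events: Dict) -> TreeNode:
        if s_node.is_leaf:
            return TreeNode(s_node.name)
        node = TreeNode()
        for child in s_node.children:
            node.add_child(on_edge(child, events))
        return node

    return at_node(species_tree.root, plan), truth


def _parallel_plan(species_tree: SpeciesTree, planted: PlantedParallel) -> Dict:
    b1, b2 = planted.pair.branch1, planted.pair.branch2
    for key in (b1, b2):
        if key not in species_tree.branch_to_node:
            raise SimulationError(f"{sorted(key)} is not a species-tree branch")
    if planted.level == "gene":
        return {b1: ({}, {}), b2: ({}, {})}
    anc_node = species_tree.lca(species_tree.node_for_branch(b1),
                                species_tree.node_for_branch(b2))
    anc_key = species_tree.branch_key(anc_node)
    return {anc_key: ({b1: ({}, {})}, {b2: ({}, {})})}


# ---------------------------------------------------------------------------
# forest-level simulation
# ---------------------------------------------------------------------------

def _name_genes(root: TreeNode, og: str, gene_species: Dict[str, str]) -> None:
    counters: Dict[str, int] = {}
    for leaf in root.leaves():
        species = leaf.name
        counters[species] = counters.get(species, 0) + 1
        gene_id = f"{og}_{species}_g{counters[species]}"
        leaf.name = gene_id
        gene_species[gene_id] = species


def _materialise_truth(og: str, raw: List[Tuple[TreeNode, FrozenSet[str]]],
                       planted: Optional[str]) -> List[TrueEvent]:
    out = []
    for node, branch in raw:
        out.append(TrueEvent(
            orthogroup=og,
            branch=branch,
            clade_a=frozenset(node.children[0].leaf_names()),
            clade_b=frozenset(node.children[1].leaf_names()),
            planted=planted,
        ))
    return out


def simulate_forest(config: SimulationConfig) -> Tuple[Forest, PlantedTruth]:
    """Simulate a gene forest with planted truth.

    Planted orthogroups (parallel pairs, then single-branch cohort) come
    first in orthogroup order; the remainder are background birth-death
    families.  Fully extinct background families are resampled so the
    orthogroup count is exact, unless ``keep_empty`` records them as
    single-gene-free entries (they are then dropped from the table but
    counted in the resampling log).  Deterministic for a fixed seed.
    """
    st = config.tree()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    orthogroups: Dict[str, FrozenSet[str]] = {}
    trees: Dict[str, GeneTree] = {}
    gene_species: Dict[str, str] = {}
    truth = PlantedTruth()

    n_parallel = config.planted_parallel.count if config.planted_parallel else 0
    n_cohort = config.planted_cohort[1] if config.planted_cohort else 0

    width = max(5, len(str(config.n_orthogroups)))
    for i in range(config.n_orthogroups):
        og = f"OG{i + 1:0{width}d}"
        if i < n_parallel:
            assert config.planted_parallel is not None
            plan = _parallel_plan(st, config.planted_parallel)
            root, raw = _forced_tree(st, plan)
            tag = f"parallel-{config.planted_parallel.level}"
        elif i < n_parallel + n_cohort:
            assert config.planted_cohort is not None
            branch = frozenset(config.planted_cohort[0])
            if branch not in st.branch_to_node:
                raise SimulationError(f"{sorted(branch)} is not a species-tree branch")
            root, raw = _forced_tree(st, {branch: ({}, {})})
            tag = "cohort"
        else:
            attempts = 0
            while True:
                root, raw = simulate_gene_tree(
                    st, config.duplication_rate, config.loss_rate, rng)
                attempts += 1
                if root is not None or config.keep_empty:
                    break
                if attempts > 10000:
                    raise SimulationError(
                        "extinction resampling failed 10000 times; "
                        "loss rate is too high"
                    )
            tag = None
            if root is None:
                continue  # keep_empty: family recorded as absent
        _name_genes(root, og, gene_species)
        genes = frozenset(root.leaf_names())
        orthogroups[og] = genes
        if len(genes) >= 2:
            trees[og] = GeneTree(root, og)
        truth.events.extend(_materialise_truth(og, raw, tag))
    forest = Forest(st, orthogroups, trees, gene_species)
    return forest, truth


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

def simulate_expression(forest: Forest, truth: PlantedTruth,
                        config: SimulationConfig,
                        ) -> Dict[str, ExpressionTable]:
    """Simulate per-species TPM tables with planted structure.

    Per gene: a log-normal baseline; a ``bs_fraction`` of genes (drawn once
    per gene, shared across species) get their BS mean multiplied by
    ``fold_change``.  For truth events on ``concordance_branch`` (default:
    the crown-grass branch) with representatives in both comparison
    species, one clade is made dominant in species 1 and the same clade in
    species 2 with probability ``concordance``; dominant/recessive leaf
    means are fixed TPM levels well above/below the 10-TPM inclusion rule.
    Planted preference and dominance are recorded in ``truth``.
    """
    xc = config.expression
    st = forest.species_tree
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    sp1, sp2 = config.concordance_species
    for sp in (sp1, sp2):
        if sp not in st.leaf_index:
            raise SimulationError(f"species {sp!r} absent from the species tree")
    branch = config.concordance_branch
    if branch is None:
        branch = st.branch_key(st.mrca_of_species([sp1, sp2]))
    branch = frozenset(branch)

    genes_by_species: Dict[str, List[str]] = {sp: [] for sp in st.leaf_names}
    for og in sorted(forest.orthogroups):
        for gene in sorted(forest.orthogroups[og]):
            genes_by_species[forest.gene_species[gene]].append(gene)

    all_genes = [g for sp in sorted(genes_by_species) for g in genes_by_species[sp]]
    is_bs = {g: bool(rng.random() < xc.bs_fraction) for g in all_genes}
    truth.bs_genes = {g for g, flag in is_bs.items() if flag}
    base_log2 = {g: math.log2(xc.tpm_scale) + rng.normal(0.0, xc.gene_sigma)
                 for g in all_genes}

    # planted leaf dominance for events on the ancestral branch
    leaf_log2: Dict[str, Dict[str, float]] = {sp1: {}, sp2: {}}
    for event in truth.events_on(branch):
        reps: Dict[str, Tuple[List[str], List[str]]] = {}
        for sp in (sp1, sp2):
            in_a = sorted(g for g in event.clade_a if forest.gene_species[g] == sp)
            in_b = sorted(g for g in event.clade_b if forest.gene_species[g] == sp)
            if in_a and in_b:
                reps[sp] = (in_a, in_b)
        if len(reps) < 2:
            continue
        if any(g in leaf_log2[sp] for sp, (in_a, in_b) in reps.items()
               for g in in_a + in_b):
            continue  # nested events: first planted wins, rest skipped
        dom1 = "A" if rng.random() < 0.5 else "B"
        dom2 = dom1 if rng.random() < xc.concordance else ("B" if dom1 == "A" else "A")
        truth.dominance[event.signature] = (dom1, dom2)
        for sp, dom in ((sp1, dom1), (sp2, dom2)):
            in_a, in_b = reps[sp]
            hi, lo = (in_a, in_b) if dom == "A" else (in_b, in_a)
            for g in hi:
                leaf_log2[sp][g] = math.log2(xc.dominant_tpm)
            for g in lo:
                leaf_log2[sp][g] = math.log2(xc.recessive_tpm)

    tables: Dict[str, ExpressionTable] = {}
    for sp in sorted(genes_by_species):
        genes = genes_by_species[sp]
        if not genes:
            continue
        conditions = (["BS"] * xc.n_replicates + ["M"] * xc.n_replicates
                      + [xc.leaf_condition] * xc.n_replicates)
        replicates = list(range(1, xc.n_replicates + 1)) * 3
        names = [f"{sp}_{cond}_{rep}" for cond, rep in zip(conditions, replicates)]
        means = np.empty((len(genes), len(names)))
        for gi, g in enumerate(genes):
            base = base_log2[g]
            bs_mean = base + (math.log2(xc.fold_change) if is_bs[g] else 0.0)
            leaf_mean = leaf_log2.get(sp, {}).get(g, base)
            for si, cond in enumerate(conditions):
                if cond == "BS":
                    means[gi, si] = bs_mean
                elif cond == "M":
                    means[gi, si] = base
                else:
                    means[gi, si] = leaf_mean
        noise = rng.normal(0.0, xc.noise_sigma, size=means.shape) \
            if xc.noise_sigma > 0 else 0.0
        values = pd.DataFrame(np.exp2(means + noise), index=genes, columns=names)
        samples = pd.DataFrame({
            "species": sp,
            "condition": conditions,
            "replicate": replicates,
        }, index=pd.Index(names, name="sample"))
        tables[sp] = ExpressionTable(values, samples)
    return tables


# ---------------------------------------------------------------------------
# fixture output in the package's own input formats
# ---------------------------------------------------------------------------

def write_forest(forest: Forest, outdir) -> None:
    """Write a forest in the exact trees_io input formats (all text)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "species_tree.nwk").write_text(
        serialize_newick(forest.species_tree.root) + "\n")
    treedir = outdir / "gene_trees"
    treedir.mkdir(exist_ok=True)
    for og in sorted(forest.trees):
        (treedir / f"{og}.nwk").write_text(forest.trees[og].to_newick() + "\n")
    with open(outdir / "orthogroups.tsv", "w") as fh:
        fh.write("orthogroup_id\tgene_id\n")
        for og in sorted(forest.orthogroups):
            for gene in sorted(forest.orthogroups[og]):
                fh.write(f"{og}\t{gene}\n")
    with open(outdir / "gene_species.tsv", "w") as fh:
        fh.write("gene_id\tspecies_id\n")
        for gene in sorted(forest.gene_species):
            fh.write(f"{gene}\t{forest.gene_species[gene]}\n")


def write_expression(tables: Dict[str, ExpressionTable], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in sorted(tables):
        tables[sp].write(outdir / f"expression_{sp}.tsv",
                         outdir / f"samples_{sp}.tsv")
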