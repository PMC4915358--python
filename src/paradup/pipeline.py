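"""Full-analysis orchestration behind a single configuration object.

``run_full_pipeline`` executes validate -> reconcile -> filter -> branch
summary -> overlap/parallel detection -> expression statistics -> term
enrichment, writing deterministic TSV outputs plus one JSON run report.
Expression stages are optional: without expression tables the tree stages
still complete and the report notes the skip.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .expression import (
    ExpressionTable,
    classify_cell_preference,
    dominance_concordance,
    preference_enrichment,
    term_enrichment,
)
from .filters import RetentionCriteria, branch_summary, filter_events
from .parallel import (
    FocalBranchPair,
    find_parallel_events,
    overlap_enrichment,
    parallel_counts,
)
from .reconcile import reconcile_forest
from .trees import (
    Forest,
    GeneTree,
    SpeciesTree,
    load_gene_species_map,
    load_orthogroup_table,
    parse_newick,
    validate_forest,
)

logger = logging.getLogger("paradup")

__all__ = ["PipelineConfig", "PipelineError", "RunReport",
           "run_full_pipeline", "analyse_forest", "load_forest"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending record."""


@dataclass
class PipelineConfig:
    """Paths, thresholds and focal branches of one pipeline run."""

    species_tree: str = ""
    orthogroups: str = ""
    gene_species: str = ""
    gene_trees_dir: str = ""
    expression: Dict[str, Dict[str, str]] = field(default_factory=dict)
    annotations: Optional[str] = None
    focal_branch1: Tuple[str, ...] = ()
    focal_branch2: Tuple[str, ...] = ()
    concordance_branch: Tuple[str, ...] = ()
    concordance_species: Tuple[str, ...] = ()
    min_evidence_species: int = 2
    require_full_retention: bool = True
    universe: str = "shared-species"       # or "all"
    alpha: float = 0.05
    min_fc: float = 2.0
    threshold_tpm: float = 10.0
    polytomy_policy: str = "reject"
    seed: int = 0
    output_dir: str = "paradup_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        for key in ("focal_branch1", "focal_branch2", "concordance_branch",
                    "concordance_species"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def criteria(self) -> RetentionCriteria:
        return RetentionCriteria(self.min_evidence_species,
                                 self.require_full_retention)

    def focal_pair(self) -> Optional[FocalBranchPair]:
        if not self.focal_branch1 or not self.focal_branch2:
            return None
        return FocalBranchPair(frozenset(self.focal_branch1),
                               frozenset(self.focal_branch2))


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    version: str
    seed: int
    counts: Dict[str, int]
    branch_summary: List[Dict]
    overlap: Optional[Dict] = None
    parallel: Optional[Dict[str, int]] = None
    preference_enrichment: Dict[str, List[Dict]] = field(default_factory=dict)
    concordance: Optional[Dict] = None
    term_enrichment_significant: Optional[int] = None
    skipped: List[str] = field(default_factory=list)
    config: Dict = field(default_factory=dict)

    def to_dict(self) -> Dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "counts": self.counts,
            "branch_summary": self.branch_summary,
            "overlap": self.overlap,
            "parallel": self.parallel,
            "preference_enrichment": self.preference_enrichment,
            "concordance": self.concordance,
            "term_enrichment_significant": self.term_enrichment_significant,
            "skipped": self.skipped,
            "config": self.config,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)


def load_forest(config: PipelineConfig) -> Forest:
    """Load and validate the forest referenced by a config."""
    try:
        species_tree = SpeciesTree(parse_newick(
            Path(config.species_tree).read_text()))
    except Exception as exc:
        raise PipelineError(f"stage load-species-tree: {exc}") from exc
    try:
        orthogroups = load_orthogroup_table(config.orthogroups)
        gene_species = load_gene_species_map(config.gene_species, species_tree)
    except Exception as exc:
        raise PipelineError(f"stage load-tables: {exc}") from exc
    trees: Dict[str, GeneTree] = {}
    tree_dir = Path(config.gene_trees_dir)
    for og, genes in orthogroups.items():
        if len(genes) < 2:
            continue
        path = tree_dir / f"{og}.nwk"
        if not path.exists():
            raise PipelineError(f"stage load-trees: no gene tree file {path}")
        try:
            trees[og] = GeneTree(parse_newick(path.read_text()), og)
        except Exception as exc:
            raise PipelineError(f"stage load-trees: {og}: {exc}") from exc
    try:
        return validate_forest(orthogroups, trees, gene_species, species_tree,
                               config.polytomy_policy)
    except Exception as exc:
        raise PipelineError(f"stage validate: {exc}") from exc


def _load_expression(config: PipelineConfig) -> Dict[str, ExpressionTable]:
    tables = {}
    for species, paths in config.expression.items():
        tables[species] = ExpressionTable.read(paths["values"], paths["samples"])
    return tables


def _float_fmt(x: float) -> str:
    return f"{x:.6g}"


def analyse_forest(forest: Forest,
                   criteria: RetentionCriteria = RetentionCriteria(),
                   pair: Optional[FocalBranchPair] = None,
                   universe: Optional[str] = None,
                   expression_tables: Optional[Dict[str, ExpressionTable]] = None,
                   annotations: Optional[Dict[str, List[str]]] = None,
                   concordance_branch: Optional[FrozenSet[str]] = None,
                   concordance_species: Optional[Tuple[str, str]] = None,
                   alpha: float = 0.05, min_fc: float = 2.0,
                   threshold_tpm: float = 10.0,
                   leaf_condition: str = "leaf",
                   seed: int = 0,
                   output_dir: Optional[Path] = None) -> RunReport:
    """Run every analysis stage on an in-memory forest.

    The tree stages always run; overlap/parallel need a focal pair and the
    expression stages need expression tables (otherwise they are skipped
    and listed in the report).  With ``output_dir`` set, deterministic TSV
    outputs and a ``report.json`` are written.
    """
    outputs: Dict[str, pd.DataFrame] = {}
    skipped: List[str] = []

    logger.info("reconcile: %d orthogroups", len(forest.orthogroups))
    catalog = reconcile_forest(forest)
    filtered = filter_events(catalog, criteria)
    counts = filtered.counts()
    counts["orthogroups"] = len(forest.orthogroups)
    counts["genes"] = forest.n_genes
    summary = branch_summary(filtered)
    outputs["events.tsv"] = filtered.to_frame()
    outputs["branch_summary.tsv"] = summary

    overlap_dict = None
    par_counts = None
    overlap_ogs: FrozenSet[str] = frozenset()
    if pair is not None:
        overlap = overlap_enrichment(filtered, pair,
                                     "all" if universe == "all" else None)
        overlap_dict = overlap.to_dict()
        parallels = find_parallel_events(filtered, pair)
        par_counts = parallel_counts(parallels)
        overlap_ogs = frozenset(p.orthogroup for p in parallels)
        outputs["overlap.tsv"] = pd.DataFrame([overlap_dict])
        outputs["parallel_events.tsv"] = pd.DataFrame(
            [p.to_dict() for p in parallels],
            columns=["orthogroup", "level", "branch1", "node1",
                     "branch2", "node2", "lineage_node"])
    else:
        skipped.append("overlap/parallel (no focal branch pair)")

    pref_summary: Dict[str, List[Dict]] = {}
    concordance_dict = None
    if expression_tables:
        for species in sorted(expression_tables):
            table = expression_tables[species]
            if not {"BS", "M"} <= set(table.samples["condition"]):
                continue
            calls = classify_cell_preference(table, species, alpha, min_fc)
            outputs[f"preference_calls_{species}.tsv"] = calls
            if pair is not None:
                for branch_name, branch in (("branch1", pair.branch1),
                                            ("branch2", pair.branch2)):
                    if species not in branch:
                        continue
                    cohort = sorted({
                        g for e in filtered.retained_on_branch(branch)
                        for g in (e.clade_a | e.clade_b)
                        if forest.gene_species[g] == species
                        and g in calls.index
                    })
                    if not cohort:
                        continue
                    enr = preference_enrichment(cohort, calls)
                    enr.insert(0, "species", species)
                    enr.insert(1, "branch", ",".join(sorted(branch)))
                    pref_summary.setdefault(branch_name, []).extend(
                        enr.to_dict("records"))
        if pref_summary:
            outputs["preference_enrichment.tsv"] = pd.DataFrame(
                [row for rows in pref_summary.values() for row in rows])
        if concordance_branch and concordance_species:
            sp1, sp2 = concordance_species
            if sp1 in expression_tables and sp2 in expression_tables:
                result = dominance_concordance(
                    filtered, frozenset(concordance_branch),
                    expression_tables[sp1], expression_tables[sp2],
                    threshold_tpm, sp1, sp2, condition=leaf_condition)
                concordance_dict = {
                    "n_assessed": result.n_assessed,
                    "n_concordant": result.n_concordant,
                    "percentage": result.percentage,
                }
                outputs["concordance.tsv"] = result.records
            else:
                skipped.append("concordance (missing species tables)")
        elif concordance_branch or concordance_species:
            skipped.append("concordance (branch and species both required)")
    else:
        skipped.append("expression (no tables supplied)")

    n_significant_terms = None
    if annotations is not None and pair is not None:
        universe_ogs = frozenset(catalog.orthogroups)
        target = overlap_ogs if overlap_ogs else filtered.retained_orthogroups()
        terms = term_enrichment(target, universe_ogs, annotations)
        outputs["term_enrichment.tsv"] = terms
        n_significant_terms = int(terms["significant"].sum()) if len(terms) else 0
    elif annotations is not None:
        skipped.append("term enrichment (no focal branch pair)")

    report = RunReport(
        version=__version__,
        seed=seed,
        counts=counts,
        branch_summary=summary.to_dict("records"),
        overlap=overlap_dict,
        parallel=par_counts,
        preference_enrichment=pref_summary,
        concordance=concordance_dict,
        term_enrichment_significant=n_significant_terms,
        skipped=skipped,
    )
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        for name in sorted(outputs):
            frame = outputs[name]
            frame.to_csv(output_dir / name, sep="\t",
                         index=bool(frame.index.name),
                         float_format="%.6g")
        (output_dir / "report.json").write_text(report.to_json() + "\n")
    return report


def run_full_pipeline(config: PipelineConfig) -> RunReport:
    """Config-driven end-to-end run (file inputs, TSV + JSON outputs)."""
    pair = config.focal_pair()
    forest = load_forest(config)
    try:
        expression_tables = _load_expression(config)
    except Exception as exc:
        raise PipelineError(f"stage load-expression: {exc}") from exc
    annotations = None
    if config.annotations:
        try:
            frame = pd.read_csv(config.annotations, sep="\t", comment="#",
                                header=None, names=["orthogroup", "term"],
                                dtype=str)
            if len(frame) and list(frame.iloc[0]) == ["orthogroup", "term"]:
                frame = frame.iloc[1:]
            annotations = {}
            for og, term in frame.itertuples(index=False):
                annotations.setdefault(og, []).append(term)
        except Exception as exc:
            raise PipelineError(f"stage load-annotations: {exc}") from exc
    report = analyse_forest(
        forest,
        criteria=config.criteria(),
        pair=pair,
        universe=config.universe,
        expression_tables=expression_tables or None,
        annotations=annotations,
        concordance_branch=frozenset(config.concordance_branch) or None,
        concordance_species=tuple(config.concordance_species) or None,
        alpha=config.alpha,
        min_fc=config.min_fc,
        threshold_tpm=config.threshold_tpm,
        seed=config.seed,
        output_dir=Path(config.output_dir),
    )
    report.config = {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in vars(config).items()}
    (Path(config.output_dir) / "report.json").write_text(report.to_json() + "\n")
    return report
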