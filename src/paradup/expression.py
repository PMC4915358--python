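"""Cell-type expression statistics for duplicate-gene cohorts.

Inputs are TPM tables (genes x samples) with a sample sheet giving species,
condition (``BS``, ``M`` or a leaf stage) and replicate for every sample.

* :func:`classify_cell_preference` calls genes bundle-sheath- or
  mesophyll-preferential from replicated BS/M TPM via Welch's t-test on
  log2(TPM + 1), a fold-change gate and Benjamini-Hochberg control.
* :func:`preference_enrichment` compares the BS/M-preferential proportion
  of a gene cohort against the genome background with an exact binomial
  test (two-sided by clipped doubling of the smaller tail).
* :func:`dominance_concordance` asks, for duplications on an ancestral
  branch, whether the same paralog clade is the more highly expressed one
  in two descendant species (duplicate pairs only count when expressed
  above a TPM threshold in both species).
* :func:`term_enrichment` runs hypergeometric ontology-term enrichment over
  orthogroup sets with BH correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .filters import FilteredCatalog
from .parallel import hypergeometric_tail, log10_hypergeometric_tail

__all__ = [
    "ExpressionTable",
    "ConcordanceResult",
    "classify_cell_preference",
    "preference_enrichment",
    "dominance_concordance",
    "bh_adjust",
    "term_enrichment",
    "significance_stars",
]

BS = "BS"
M = "M"
NONE = "none"


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionTable:
    """Per-gene TPM values with per-sample metadata.

    ``values``: DataFrame genes x samples (non-negative TPM).
    ``samples``: DataFrame indexed by sample name with columns
    ``species``, ``condition``, ``replicate``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"species", "condition", "replicate"} - set(self.samples.columns)
        if missing:
            raise ExpressionError(f"sample sheet lacks columns: {sorted(missing)}")
        if list(self.values.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        if (self.values.values < 0).any():
            raise ExpressionError("TPM values must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def species_set(self) -> FrozenSet[str]:
        return frozenset(self.samples["species"])

    def single_species(self) -> str:
        species = self.species_set()
        if len(species) != 1:
            raise ExpressionError(
                "table holds several species; pass the species explicitly"
            )
        return next(iter(species))

    def condition_values(self, species: str, condition: str) -> pd.DataFrame:
        mask = ((self.samples["species"] == species)
                & (self.samples["condition"] == condition))
        cols = self.samples.index[mask]
        return self.values[cols]

    def mean_tpm(self, species: Optional[str] = None,
                 condition: Optional[str] = None) -> pd.Series:
        mask = pd.Series(True, index=self.samples.index)
        if species is not None:
            mask &= self.samples["species"] == species
        if condition is not None:
            mask &= self.samples["condition"] == condition
        cols = self.samples.index[mask]
        if not len(cols):
            raise ExpressionError(
                f"no samples for species={species!r}, condition={condition!r}"
            )
        return self.values[cols].mean(axis=1)

    def write(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(samples_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, values_path, samples_path) -> "ExpressionTable":
        values = pd.read_csv(values_path, sep="\t", index_col=0, comment="#")
        samples = pd.read_csv(samples_path, sep="\t", index_col=0, comment="#")
        return cls(values, samples)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_log_tpm(bs: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Two-sided Welch p per gene on log2(TPM+1); degenerate-variance guard.

    When both groups have zero variance the t statistic is undefined; the
    guard reports p=0 for unequal means and p=1 for equal means, which makes
    noiseless simulations exactly recoverable.
    """
    a = np.log2(bs + 1.0)
    b = np.log2(m + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant replicate groups trip scipy's precision warning; the
        # degenerate cases are overwritten by the guard below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[zero_var & equal_means] = 1.0
    p[zero_var & ~equal_means] = 0.0
    p[np.isnan(p)] = 1.0
    return p


def classify_cell_preference(table: ExpressionTable, species: Optional[str] = None,
                             alpha: float = 0.05, min_fc: float = 2.0,
                             floor_tpm: float = 1.0) -> pd.DataFrame:
    """Call genes BS-/M-preferential from replicated BS and M TPM.

    Returns a DataFrame indexed by gene with columns ``call`` (BS/M/none),
    ``fold_change`` (mean BS TPM over mean M TPM), ``p_value`` and
    ``p_adjusted`` (BH across all tested genes).  Genes below ``floor_tpm``
    mean TPM in both conditions are not tested and get call ``none``.
    Antisymmetric under swapping the BS and M labels.
    """
    if species is None:
        species = table.single_species()
    bs = table.condition_values(species, BS)
    m = table.condition_values(species, M)
    for name, frame in ((BS, bs), (M, m)):
        if frame.shape[1] < 2:
            raise ExpressionError(
                f"species {species!r} needs >= 2 {name} replicates "
                f"(found {frame.shape[1]})"
            )
    bs_mean = bs.mean(axis=1).to_numpy()
    m_mean = m.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(m_mean > 0, bs_mean / m_mean,
                        np.where(bs_mean > 0, np.inf, np.nan))
    tested = (bs_mean >= floor_tpm) | (m_mean >= floor_tpm)
    p = np.full(len(table.genes), np.nan)
    padj = np.full(len(table.genes), np.nan)
    if tested.any():
        p[tested] = _welch_log_tpm(bs.to_numpy()[tested], m.to_numpy()[tested])
        padj[tested] = bh_adjust(p[tested])
    call = np.full(len(table.genes), NONE, dtype=object)
    significant = tested & (padj <= alpha)
    call[significant & (fold >= min_fc)] = BS
    call[significant & (fold <= 1.0 / min_fc)] = M
    return pd.DataFrame(
        {"call": call, "fold_change": fold, "p_value": p, "p_adjusted": padj},
        index=table.genes,
    )


def _binomial_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided exact binomial p by clipped doubling of the smaller tail.

    Degenerate backgrounds (p0 of 0 or 1) cannot be doubled; the guard
    reports p=1 when the observation matches the degenerate expectation and
    p=0 otherwise.
    """
    if not 0 <= p0 <= 1:
        raise ValueError("background proportion must lie in [0, 1]")
    if p0 in (0.0, 1.0):
        return 1.0 if k == round(n * p0) else 0.0
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def preference_enrichment(genes: Iterable[str], calls: pd.DataFrame,
                          background: Optional[pd.DataFrame] = None
                          ) -> pd.DataFrame:
    """Test a gene cohort for BS/M-preference enrichment against background.

    ``calls`` is the output of :func:`classify_cell_preference` covering the
    cohort; ``background`` defaults to ``calls`` (all classified genes).
    Returns one row per cell type with the cohort and background
    proportions, the exact binomial two-sided p and significance stars.
    """
    gene_list = sorted(set(genes))
    if not gene_list:
        raise ExpressionError("empty gene set")
    if background is None:
        background = calls
    missing = [g for g in gene_list if g not in calls.index]
    if missing:
        raise ExpressionError(
            f"genes without preference calls: {missing[:5]}..."
        )
    subset = calls.loc[gene_list]
    rows = []
    n = len(subset)
    n_bg = len(background)
    for cell_type in (BS, M):
        k = int((subset["call"] == cell_type).sum())
        p0 = float((background["call"] == cell_type).sum()) / n_bg
        p = _binomial_two_sided(k, n, p0)
        rows.append({
            "cell_type": cell_type,
            "n_set": n,
            "k_set": k,
            "set_proportion": k / n,
            "background_proportion": p0,
            "p_value": p,
            "stars": significance_stars(p),
        })
    return pd.DataFrame(rows)


@dataclass
class ConcordanceResult:
    """Expression-dominance concordance of duplicate pairs in two species."""

    n_assessed: int
    n_concordant: int
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if not 0 <= self.n_concordant <= self.n_assessed:
            raise ValueError("n_concordant must lie in [0, n_assessed]")

    @property
    def percentage(self) -> float:
        if self.n_assessed == 0:
            return float("nan")
        return 100.0 * self.n_concordant / self.n_assessed


def dominance_concordance(filtered: FilteredCatalog, branch: FrozenSet[str],
                          table1: ExpressionTable, table2: ExpressionTable,
                          threshold_tpm: float = 10.0,
                          species1: Optional[str] = None,
                          species2: Optional[str] = None,
                          condition: Optional[str] = None) -> ConcordanceResult:
    """Concordance of the dominant duplicate across two descendant species.

    For every retained event on ``branch``: the representative of each
    paralog clade in each species is that species' highest-TPM gene of the
    clade (mean TPM over ``condition`` samples, or all samples).  An event
    is assessed only when, in both species, the higher representative
    exceeds ``threshold_tpm``; exact ties are excluded.  Concordant means
    the same clade dominates in both species.  Invariant under a consistent
    clade A/B relabelling.
    """
    branch = frozenset(branch)
    st = filtered.species_tree
    branch_node = st.node_for_branch(branch)
    sp1 = species1 if species1 is not None else table1.single_species()
    sp2 = species2 if species2 is not None else table2.single_species()
    for sp in (sp1, sp2):
        if sp not in branch:
            raise ExpressionError(
                f"species {sp!r} does not descend from branch {sorted(branch)}"
            )
    del branch_node
    expr1 = table1.mean_tpm(condition=condition)
    expr2 = table2.mean_tpm(condition=condition)
    gene_species = filtered.catalog.gene_species

    def representative(clade: FrozenSet[str], expr: pd.Series, sp: str
                       ) -> Tuple[Optional[str], float]:
        members = [g for g in clade if gene_species.get(g) == sp and g in expr.index]
        if not members:
            return None, float("nan")
        # deterministic arg-max: value first, then gene id
        best = max(members, key=lambda g: (expr[g], g))
        return best, float(expr[best])

    rows = []
    n_assessed = 0
    n_concordant = 0
    for event in filtered.retained_on_branch(branch):
        record = {"orthogroup": event.orthogroup, "node_index": event.node_index}
        dominant = {}
        included = True
        for label, expr, sp in (("1", expr1, sp1), ("2", expr2, sp2)):
            _, tpm_a = representative(event.clade_a, expr, sp)
            _, tpm_b = representative(event.clade_b, expr, sp)
            record[f"tpm_a_sp{label}"] = tpm_a
            record[f"tpm_b_sp{label}"] = tpm_b
            if math.isnan(tpm_a) or math.isnan(tpm_b):
                included = False
                continue
            if max(tpm_a, tpm_b) <= threshold_tpm or tpm_a == tpm_b:
                included = False
                continue
            dominant[label] = "A" if tpm_a > tpm_b else "B"
        record["dominant_sp1"] = dominant.get("1")
        record["dominant_sp2"] = dominant.get("2")
        record["included"] = included
        if included:
            n_assessed += 1
            concordant = dominant["1"] == dominant["2"]
            record["concordant"] = concordant
            n_concordant += int(concordant)
        else:
            record["concordant"] = None
        rows.append(record)
    records = pd.DataFrame(rows)
    return ConcordanceResult(n_assessed, n_concordant, records)


def term_enrichment(og_set: Iterable[str], universe: Iterable[str],
                    annotations: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Hypergeometric term enrichment over orthogroup sets with BH control.

    ``annotations`` maps orthogroup -> terms; rows for orthogroups outside
    the universe are dropped with a warning.  One row per term occurring in
    the set: k (set hits), K (universe hits), n (set size), N (universe
    size), p (upper-tail hypergeometric), adjusted p (BH across tested
    terms) and a ``significant`` flag at adjusted p <= 0.05.
    """
    og_set = frozenset(og_set)
    universe = frozenset(universe)
    if not og_set <= universe:
        raise ValueError("orthogroup set must be a subset of the universe")
    stray = sorted(set(annotations) - universe)
    if stray:
        warnings.warn(
            f"{len(stray)} annotated orthogroups outside the universe were "
            f"ignored (e.g. {stray[:3]})",
            stacklevel=2,
        )
    term_universe: Dict[str, set] = {}
    for og in universe:
        for term in annotations.get(og, ()):
            term_universe.setdefault(term, set()).add(og)
    N = len(universe)
    n = len(og_set)
    rows = []
    for term in sorted(term_universe):
        hits = term_universe[term]
        k = len(hits & og_set)
        if k == 0:
            continue
        K = len(hits)
        rows.append({
            "term": term, "k": k, "K": K, "n": n, "N": N,
            "p_value": hypergeometric_tail(N, K, n, k),
            "log10_p": log10_hypergeometric_tail(N, K, n, k),
        })
    frame = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N",
                                        "p_value", "log10_p"])
    if len(frame):
        frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy())
        frame["significant"] = frame["p_adjusted"] <= 0.05
    else:
        frame["p_adjusted"] = []
        frame["significant"] = []
    return frame
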