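import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from paradup import monocots
from paradup.expression import (
    ConcordanceResult,
    ExpressionError,
    ExpressionTable,
    bh_adjust,
    classify_cell_preference,
    dominance_concordance,
    preference_enrichment,
    term_enrichment,
)
from paradup.filters import filter_events
from paradup.reconcile import reconcile_forest
from paradup.simulate import (
    ExpressionConfig,
    SimulationConfig,
    simulate_expression,
    simulate_forest,
)

from oracles import stepup_bh


def make_table(genes, bs, m, leaf=None, species="A"):
    """Expression table from per-gene replicate tuples."""
    conditions = (["BS"] * len(bs[0]) + ["M"] * len(m[0])
                  + (["leaf"] * len(leaf[0]) if leaf else []))
    columns = [f"{species}_{c}_{i}" for i, c in enumerate(conditions)]
    rows = []
    for gi in range(len(genes)):
        row = list(bs[gi]) + list(m[gi]) + (list(leaf[gi]) if leaf else [])
        rows.append(row)
    values = pd.DataFrame(rows, index=genes, columns=columns)
    samples = pd.DataFrame({
        "species": species,
        "condition": conditions,
        "replicate": range(len(conditions)),
    }, index=pd.Index(columns, name="sample"))
    return ExpressionTable(values, samples)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert bh_adjust([0.001, 1.0]) == pytest.approx([0.002, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_closed_form_step_up(self, p):
        p = np.asarray(p)
        assert bh_adjust(p) == pytest.approx(stepup_bh(p), abs=1e-12)

    def test_idempotent_after_capping(self):
        rng = np.random.default_rng(0)
        p = rng.random(25)
        once = bh_adjust(p)
        assert bh_adjust(once) == pytest.approx(
            stepup_bh(once), abs=1e-12)


class TestClassifyCellPreference:
    def test_strong_bs_gene_called(self):
        table = make_table(["g1"], bs=[(100, 110, 90)], m=[(10, 12, 8)])
        calls = classify_cell_preference(table, alpha=0.05, min_fc=2)
        assert calls.loc["g1", "call"] == "BS"
        assert calls.loc["g1", "fold_change"] == pytest.approx(10.0)
        assert calls.loc["g1", "p_adjusted"] <= 0.05

    def test_identical_conditions_not_called(self):
        table = make_table(["g1"], bs=[(50, 60, 55)], m=[(50, 60, 55)])
        assert classify_cell_preference(table).loc["g1", "call"] == "none"

    def test_all_zero_gene_floored(self):
        table = make_table(["g1"], bs=[(0, 0, 0)], m=[(0, 0, 0)])
        calls = classify_cell_preference(table)
        assert calls.loc["g1", "call"] == "none"
        assert math.isnan(calls.loc["g1", "p_value"])

    def test_antisymmetric_under_label_swap(self):
        table = make_table(["g1", "g2", "g3"],
                           bs=[(100, 110, 90), (10, 12, 8), (40, 44, 36)],
                           m=[(10, 12, 8), (100, 110, 90), (40, 42, 38)])
        swapped_samples = table.samples.copy()
        swapped_samples["condition"] = swapped_samples["condition"].map(
            {"BS": "M", "M": "BS"})
        swapped = ExpressionTable(table.values, swapped_samples)
        calls = classify_cell_preference(table)
        flipped = classify_cell_preference(swapped)
        mirror = {"BS": "M", "M": "BS", "none": "none"}
        assert list(flipped["call"]) == [mirror[c] for c in calls["call"]]

    def test_missing_condition_raises(self):
        table = make_table(["g1"], bs=[(1, 2, 3)], m=[(1, 2, 3)])
        only_bs = ExpressionTable(
            table.values.iloc[:, :3], table.samples.iloc[:3])
        with pytest.raises(ExpressionError):
            classify_cell_preference(only_bs)


class TestPreferenceEnrichment:
    def _calls(self, n_bs, n_m, n_none):
        calls = ["BS"] * n_bs + ["M"] * n_m + ["none"] * n_none
        genes = [f"g{i}" for i in range(len(calls))]
        return pd.DataFrame({"call": calls}, index=genes)

    def test_doubled_binomial_tail(self):
        background = self._calls(25, 25, 50)   # BS proportion 0.25
        subset = [f"g{i}" for i in range(20)]  # 15 BS in a set of 20
        calls = background.copy()
        calls.loc[subset[:15], "call"] = "BS"
        calls.loc[subset[15:], "call"] = "none"
        result = preference_enrichment(subset, calls, background)
        row = result.set_index("cell_type").loc["BS"]
        from scipy.stats import binom
        expected = min(1.0, 2 * binom.sf(14, 20, 0.25))
        assert row["p_value"] == pytest.approx(expected)
        assert row["stars"] == "***"

    def test_background_rate_set_is_not_significant(self):
        calls = self._calls(20, 20, 60)
        subset = (["g0", "g1"]                       # 2 BS
                  + [f"g{i}" for i in range(20, 22)]  # 2 M
                  + [f"g{i}" for i in range(40, 46)])  # 6 none
        result = preference_enrichment(subset, calls)
        assert (result["p_value"] >= 0.05).all()
        assert (result["stars"] == "").all()

    def test_degenerate_background_guard(self):
        calls = self._calls(3, 0, 17)
        result = preference_enrichment(["g0", "g1"], calls,
                                       background=self._calls(0, 0, 10))
        row = result.set_index("cell_type").loc["BS"]
        assert row["background_proportion"] == 0.0
        assert row["p_value"] == 0.0  # observed hits are impossible under H0

    def test_empty_set_raises(self):
        with pytest.raises(ExpressionError):
            preference_enrichment([], self._calls(1, 1, 1))


class TestDominanceConcordance:
    def _fixture(self, seed=0, n=30, concordance=0.8, sigma=0.1):
        config = SimulationConfig(
            n_orthogroups=n, duplication_rate=0.0, loss_rate=0.0, seed=seed,
            planted_cohort=(monocots.POACEAE, n),
            expression=ExpressionConfig(concordance=concordance,
                                        noise_sigma=sigma))
        forest, truth = simulate_forest(config)
        filtered = filter_events(reconcile_forest(forest))
        tables = simulate_expression(forest, truth, config)
        return filtered, truth, tables

    def test_fully_concordant_cohort(self):
        filtered, truth, tables = self._fixture(n=10, concordance=1.0)
        result = dominance_concordance(
            filtered, monocots.POACEAE, tables["Zmays"], tables["Osativa"],
            condition="leaf")
        assert result.n_assessed == 10
        assert result.n_concordant == 10
        assert result.percentage == pytest.approx(100.0)

    def test_planted_truth_matches_call_by_call(self):
        filtered, truth, tables = self._fixture(n=40, concordance=0.7, seed=4)
        result = dominance_concordance(
            filtered, monocots.POACEAE, tables["Zmays"], tables["Osativa"],
            condition="leaf")
        planted_concordant = sum(d1 == d2 for d1, d2 in truth.dominance.values())
        assert result.n_assessed == len(truth.dominance)
        assert result.n_concordant == planted_concordant

    def test_low_expression_events_excluded(self):
        filtered, truth, tables = self._fixture(n=5, concordance=1.0, sigma=0.0)
        # push one event's genes in both species below the 10 TPM threshold
        og = sorted(filtered.retained_orthogroups(monocots.POACEAE))[0]
        for sp in ("Zmays", "Osativa"):
            table = tables[sp]
            leaf_cols = table.samples.index[table.samples.condition == "leaf"]
            member = [g for g in table.genes if g.startswith(og)]
            table.values.loc[member, leaf_cols] = 1.0
        result = dominance_concordance(
            filtered, monocots.POACEAE, tables["Zmays"], tables["Osativa"],
            condition="leaf")
        assert result.n_assessed == 4

    def test_species_outside_branch_rejected(self):
        filtered, truth, tables = self._fixture(n=3)
        with pytest.raises(ExpressionError, match="descend"):
            dominance_concordance(
                filtered, monocots.ANDROPOGONEAE,
                tables["Zmays"], tables["Osativa"], condition="leaf")

    def test_relabelling_invariance(self):
        filtered, truth, tables = self._fixture(n=15, concordance=0.6, seed=9)
        result = dominance_concordance(
            filtered, monocots.POACEAE, tables["Zmays"], tables["Osativa"],
            condition="leaf")
        # swap clade A and B consistently on every retained event
        for event in filtered.events:
            event.clade_a, event.clade_b = event.clade_b, event.clade_a
            event.species_a, event.species_b = event.species_b, event.species_a
        swapped = dominance_concordance(
            filtered, monocots.POACEAE, tables["Zmays"], tables["Osativa"],
            condition="leaf")
        assert swapped.n_assessed == result.n_assessed
        assert swapped.n_concordant == result.n_concordant

    def test_percentage_arithmetic(self):
        result = ConcordanceResult(n_assessed=1210, n_concordant=893)
        assert result.percentage == pytest.approx(100 * 893 / 1210)
        with pytest.raises(ValueError):
            ConcordanceResult(n_assessed=5, n_concordant=6)


class TestTermEnrichment:
    def test_set_equal_universe_gives_p_one(self):
        universe = [f"OG{i}" for i in range(20)]
        annot = {og: ["T1"] for og in universe[:5]}
        result = term_enrichment(universe, universe, annot)
        assert result.set_index("term").loc["T1", "p_value"] == pytest.approx(1.0)

    def test_perfect_pullout_closed_form(self):
        universe = [f"OG{i}" for i in range(20)]
        annot = {og: ["T1"] for og in universe[:5]}
        result = term_enrichment(universe[:5], universe, annot)
        assert result.set_index("term").loc["T1", "p_value"] == pytest.approx(
            1 / 15504)  # 1 / C(20, 5)

    def test_annotations_outside_universe_warn(self):
        universe = ["OG1", "OG2"]
        annot = {"OG1": ["T1"], "OGX": ["T2"]}
        with pytest.warns(UserWarning, match="outside the universe"):
            result = term_enrichment(["OG1"], universe, annot)
        assert list(result["term"]) == ["T1"]

    def test_set_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            term_enrichment(["OGX"], ["OG1"], {})


class TestSimulatedRecovery:
    def test_noiseless_preference_recovery(self):
        config = SimulationConfig(
            n_orthogroups=80, duplication_rate=0.0, loss_rate=0.0, seed=6,
            expression=ExpressionConfig(bs_fraction=0.3, noise_sigma=0.0))
        forest, truth = simulate_forest(config)
        tables = simulate_expression(forest, truth, config)
        for sp in ("Zmays", "Osativa"):
            calls = classify_cell_preference(tables[sp])
            called_bs = set(calls.index[calls["call"] == "BS"])
            assert called_bs == {g for g in truth.bs_genes
                                 if g in set(calls.index)}

    def test_planted_fraction_recovered_with_noise(self):
        config = SimulationConfig(
            n_orthogroups=300, duplication_rate=0.0, loss_rate=0.0, seed=8,
            expression=ExpressionConfig(bs_fraction=0.3, noise_sigma=0.25))
        forest, truth = simulate_forest(config)
        tables = simulate_expression(forest, truth, config)
        calls = pd.concat([classify_cell_preference(tables[sp])
                           for sp in sorted(tables)])
        fraction = (calls["call"] == "BS").mean()
        n = len(calls)
        se = math.sqrt(0.3 * 0.7 / n)
        assert abs(fraction - 0.3) <= 2 * se + 0.02
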