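import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from paradup import monocots
from paradup.filters import filter_events
from paradup.parallel import (
    FocalBranchPair,
    find_parallel_events,
    hypergeometric_tail,
    log10_hypergeometric_tail,
    overlap_enrichment,
    parallel_counts,
    same_gene_parallel,
)
from paradup.reconcile import reconcile_forest, reconcile_gene_tree
from paradup.simulate import PlantedParallel, SimulationConfig, simulate_forest
from paradup.trees import GeneTree

from conftest import toy_forest
from oracles import exhaustive_hypergeom_tail


class TestHypergeometricTail:
    def test_small_case_exact_fraction(self):
        assert hypergeometric_tail(10, 3, 4, 2) == pytest.approx(70 / 210)

    def test_k_zero_is_one(self):
        assert hypergeometric_tail(50, 10, 5, 0) == 1.0

    def test_impossible_k_is_zero(self):
        assert hypergeometric_tail(10, 3, 4, 4) == 0.0
        assert log10_hypergeometric_tail(10, 3, 4, 4) == -math.inf

    def test_inconsistent_counts_raise(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(5, 7, 2, 1)
        with pytest.raises(ValueError):
            hypergeometric_tail(10, 3, 4, -1)

    def test_matches_enumeration_small_universes(self, rng):
        """Spot-checked against draw-by-draw enumeration (N <= 9 here; the
        complete N <= 12 sweep runs in the acceptance suite)."""
        for _ in range(60):
            N = rng.randint(1, 9)
            K = rng.randint(0, N)
            n = rng.randint(0, N)
            k = rng.randint(0, min(K, n) + 1)
            assert hypergeometric_tail(N, K, n, k) == pytest.approx(
                exhaustive_hypergeom_tail(N, K, n, k), abs=1e-12)

    def test_point_masses_sum_to_one(self):
        for N, K, n in [(500, 120, 60), (300, 7, 150), (100, 100, 13)]:
            support = np.arange(max(0, n + K - N), min(K, n) + 1)
            total = hypergeom.pmf(support, N, K, n).sum()
            assert total == pytest.approx(1.0, abs=1e-12)
            # tail at lower support bound covers everything
            assert hypergeometric_tail(N, K, n, int(support[0])) == 1.0

    def test_extreme_tail_representable_in_log_space(self):
        log10p = log10_hypergeometric_tail(13773, 381, 225, 41)
        assert math.isfinite(log10p)
        assert log10p < -20


class TestOverlapEnrichment:
    def _filtered(self, planted=5, level="gene", n=60, seed=5, lam=0.05):
        config = SimulationConfig(
            n_orthogroups=n, duplication_rate=lam, loss_rate=0.0, seed=seed,
            planted_parallel=PlantedParallel(monocots.c4_focal_pair(),
                                             planted, level))
        forest, truth = simulate_forest(config)
        return filter_events(reconcile_forest(forest)), truth

    def test_saturated_overlap_has_p_one(self, toy_species_tree):
        filtered, _ = self._filtered(planted=10, n=10, lam=0.0)
        result = overlap_enrichment(filtered, monocots.c4_focal_pair(),
                                    universe="all")
        assert result.k_obs == result.K == result.n == 10
        assert result.N == 10
        assert result.expected == pytest.approx(10.0)
        assert result.p_value == pytest.approx(1.0)

    def test_expected_is_nk_over_N(self):
        filtered, _ = self._filtered()
        result = overlap_enrichment(filtered, monocots.c4_focal_pair(),
                                    universe="all")
        assert result.expected == pytest.approx(result.n * result.K / result.N)
        assert 0 <= result.k_obs <= min(result.K, result.n) <= result.N
        assert 0 <= result.p_value <= 1

    def test_universe_must_cover_event_orthogroups(self):
        filtered, _ = self._filtered()
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment(filtered, monocots.c4_focal_pair(),
                               universe=["OG00001"])

    def test_empty_universe_raises(self, monocot_tree):
        forest = toy_forest(monocot_tree, {"z1": "Zmays", "o1": "Osativa"},
                            {"OG1": "(z1,o1);"})
        filtered = filter_events(reconcile_forest(forest))
        with pytest.raises(ValueError, match="empty"):
            overlap_enrichment(filtered, monocots.c4_focal_pair(), universe=[])

    def test_nested_focal_branches_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            FocalBranchPair(frozenset({"A", "B"}), frozenset({"A", "B", "C"}))


class TestSameGeneParallel:
    def _monocot_forest(self, newick, gene_species, monocot_tree):
        return toy_forest(monocot_tree, gene_species, {"OG1": newick})

    def test_orthologous_duplications_are_parallel(self, monocot_tree):
        # one ancestral gene; independent duplications in each C4 clade
        newick = ("(((z1,s1),(z2,s2)),((i1,v1),(i2,v2)));")
        gm = {"z1": "Zmays", "z2": "Zmays", "s1": "Sbicolor", "s2": "Sbicolor",
              "i1": "Sitalica", "i2": "Sitalica",
              "v1": "Pvirgatum", "v2": "Pvirgatum"}
        forest = self._monocot_forest(newick, gm, monocot_tree)
        filtered = filter_events(reconcile_forest(forest))
        rtree = filtered.catalog.trees["OG1"]
        d_andro = next(e for e in filtered.retained_events
                       if e.branch == monocots.ANDROPOGONEAE)
        d_pani = next(e for e in filtered.retained_events
                      if e.branch == monocots.PANICEAE)
        assert same_gene_parallel(rtree, d_andro.node_index, d_pani.node_index)
        # symmetry
        assert same_gene_parallel(rtree, d_pani.node_index, d_andro.node_index)

    def test_duplications_in_different_paralogs_are_not_parallel(
            self, monocot_tree):
        # older duplication at the Panicoideae ancestor separates the two
        newick = ("((((z1,s1),(z2,s2)),(i0,v0)),((z0,s0),((i1,v1),(i2,v2))));")
        gm = {"z0": "Zmays", "z1": "Zmays", "z2": "Zmays",
              "s0": "Sbicolor", "s1": "Sbicolor", "s2": "Sbicolor",
              "i0": "Sitalica", "i1": "Sitalica", "i2": "Sitalica",
              "v0": "Pvirgatum", "v1": "Pvirgatum", "v2": "Pvirgatum"}
        forest = self._monocot_forest(newick, gm, monocot_tree)
        filtered = filter_events(reconcile_forest(forest))
        rtree = filtered.catalog.trees["OG1"]
        d_andro = next(e for e in filtered.retained_events
                       if e.branch == monocots.ANDROPOGONEAE)
        d_pani = next(e for e in filtered.retained_events
                      if e.branch == monocots.PANICEAE)
        assert not same_gene_parallel(rtree, d_andro.node_index,
                                      d_pani.node_index)

    def test_ancestor_descendant_pair_is_not_parallel(self, toy_species_tree,
                                                      toy_gene_species):
        rec = reconcile_gene_tree(
            GeneTree.from_newick("((a1,a2),a3);"),
            toy_species_tree, toy_gene_species, "OG1")
        dups = [e.node_index for e in rec.events]
        assert len(dups) == 2
        assert not same_gene_parallel(rec, dups[0], dups[1])


class TestFindParallelEvents:
    def test_planted_gene_level_counts(self):
        config = SimulationConfig(
            n_orthogroups=100, duplication_rate=0.0, loss_rate=0.0, seed=2,
            planted_parallel=PlantedParallel(monocots.c4_focal_pair(), 5, "gene"))
        forest, _ = simulate_forest(config)
        filtered = filter_events(reconcile_forest(forest))
        events = find_parallel_events(filtered, monocots.c4_focal_pair())
        counts = parallel_counts(events)
        assert counts == {"orthogroup_level": 5, "gene_level": 5}

    def test_planted_orthogroup_level_is_not_gene_level(self):
        config = SimulationConfig(
            n_orthogroups=100, duplication_rate=0.0, loss_rate=0.0, seed=2,
            planted_parallel=PlantedParallel(monocots.c4_focal_pair(), 3,
                                             "orthogroup"))
        forest, _ = simulate_forest(config)
        filtered = filter_events(reconcile_forest(forest))
        events = find_parallel_events(filtered, monocots.c4_focal_pair())
        counts = parallel_counts(events)
        assert counts == {"orthogroup_level": 3, "gene_level": 0}

    def test_no_events_on_one_branch_gives_empty_list(self):
        config = SimulationConfig(
            n_orthogroups=20, duplication_rate=0.0, loss_rate=0.0, seed=2,
            planted_cohort=(monocots.ANDROPOGONEAE, 5))
        forest, _ = simulate_forest(config)
        filtered = filter_events(reconcile_forest(forest))
        assert find_parallel_events(filtered, monocots.c4_focal_pair()) == []


class TestCalibrationNull:
    def test_null_rejection_rate_is_conservative(self):
        """Events assigned independently at fixed per-branch rates: the
        exact upper-tail test on discrete support rejects at <= alpha plus
        Monte-Carlo error (reduced-scale replicate of the acceptance check)."""
        rng = np.random.default_rng(99)
        alpha = 0.05
        n_rep = 150
        N = 500
        rejections = 0
        for _ in range(n_rep):
            on1 = rng.random(N) < 0.1
            on2 = rng.random(N) < 0.1
            k = int((on1 & on2).sum())
            p = hypergeometric_tail(N, int(on1.sum()), int(on2.sum()), k)
            rejections += p <= alpha
        se = math.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep <= alpha + 3 * se
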