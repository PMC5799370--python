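"""Proximity statistic, null model, z/p conversion and FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import netmed as nm
from netmed.proximity import _observed_with_drops

from conftest import random_interactome


class TestObservedProximity:
    def test_query_inside_disease_genes_is_zero(self, path_graph):
        assert nm.observed_proximity(path_graph, {"A", "B"}, {"A", "B", "C"}) == 0.0

    def test_single_protein_reduces_to_min_distance(self, path_graph):
        d = nm.observed_proximity(path_graph, {"A"}, {"C", "D"})
        assert d == nm.min_distance_to_set(path_graph, "A", {"C", "D"})

    def test_mean_of_min_distances(self):
        # star: q1 at 1 hop and q2 at 3 hops from the nearest disease gene
        g = nm.Interactome.from_edges(
            [("q1", "d1"), ("q2", "x1"), ("x1", "x2"), ("x2", "d1"), ("d1", "d2")])
        assert nm.observed_proximity(g, {"q1", "q2"}, {"d1", "d2"}) == 2.0

    def test_unreachable_protein_dropped_from_mean(self, caplog):
        g = nm.Interactome.from_edges([("q1", "d1"), ("q2", "lonely")])
        with caplog.at_level("WARNING"):
            d, dropped = _observed_with_drops(g, {"q1", "q2"}, {"d1"})
        assert d == 1.0 and dropped == 1
        assert "unreachable" in caplog.text

    def test_no_finite_distance_error(self):
        g = nm.Interactome.from_edges([("q1", "q2"), ("d1", "d2")])
        with pytest.raises(nm.NoFiniteDistanceError):
            nm.observed_proximity(g, {"q1", "q2"}, {"d1", "d2"})

    def test_shortcut_edge_never_increases_distance(self):
        g = random_interactome(60, 0.04, seed=2)
        nodes = g.node_list()
        query, disease = set(nodes[:3]), set(nodes[10:25])
        try:
            before = nm.observed_proximity(g, query, disease)
        except nm.NoFiniteDistanceError:
            pytest.skip("disconnected draw")
        for q in query:
            g.graph.add_edge(q, nodes[10])
        after = nm.observed_proximity(g, query, disease)
        assert after <= before


class TestNullSampling:
    def test_same_seed_identical_replicates(self, default_scenario):
        sc = default_scenario
        cfg = nm.ProximityConfig(n_random=50, master_seed=5)
        a = nm.sample_null(sc.interactome, sc.query,
                           sc.disease_genes["disease_01"], cfg)
        b = nm.sample_null(sc.interactome, sc.query,
                           sc.disease_genes["disease_01"], cfg)
        np.testing.assert_array_equal(a, b)

    def test_disease_genes_covering_graph_forces_zero(self, path_graph):
        cfg = nm.ProximityConfig(n_random=10, master_seed=1)
        null = nm.sample_null(path_graph, {"A"}, path_graph.nodes, cfg)
        np.testing.assert_array_equal(null, np.zeros(10))

    def test_query_side_randomization_runs(self, default_scenario):
        sc = default_scenario
        cfg = nm.ProximityConfig(n_random=30, randomize_side="query_proteins",
                                 master_seed=3)
        null = nm.sample_null(sc.interactome, sc.query,
                              sc.disease_genes["disease_02"], cfg)
        assert null.shape == (30,) and np.isfinite(null).all()

    def test_degree_matched_draws_stay_in_bins(self):
        g = random_interactome(120, 0.06, seed=8)
        bins = nm.build_degree_bins(g, min_occupancy=30)
        nodes = g.node_list()
        cfg = nm.ProximityConfig(n_random=20, matching="size_and_degree",
                                 master_seed=2, min_bin_occupancy=30)
        null = nm.sample_null(g, set(nodes[:2]), set(nodes[5:15]), cfg,
                              degree_bins=bins)
        assert null.shape == (20,)

    def test_null_calibration_on_random_sets(self):
        """Random query vs random disease genes: z is approximately standard
        normal (40-trial smoke version of the 200-trial acceptance check)."""
        zs = []
        for trial in range(40):
            g = random_interactome(200, 0.03, seed=trial)
            rng = np.random.default_rng(900 + trial)
            nodes = g.node_list()
            disease = set(rng.choice(nodes, size=20, replace=False))
            query = set(rng.choice(nodes, size=3, replace=False))
            cfg = nm.ProximityConfig(n_random=300, master_seed=5000 + trial)
            d, _ = _observed_with_drops(g, query, disease)
            null = nm.sample_null(g, query, disease, cfg)
            zs.append(nm.zscore(d, null[np.isfinite(null)]))
        zs = np.asarray(zs)
        assert abs(zs.mean()) < 0.35
        assert 0.6 < zs.std(ddof=1) < 1.5


class TestZScore:
    def test_zero_when_equal_to_null_mean(self):
        assert nm.zscore(2.0, [1.0, 2.0, 3.0]) == 0.0

    def test_direct_formula(self):
        # mean 3.0, sd 0.5 -> z = (2.0 - 3.0)/0.5 = -2
        null = [2.5, 3.5, 2.5, 3.5, 3.0, 3.0]
        sd = np.std(null, ddof=1)
        assert nm.zscore(2.0, null) == pytest.approx((2.0 - 3.0) / sd)

    def test_constant_null_gives_signed_infinity(self):
        assert nm.zscore(5.0, [2.0, 2.0, 2.0]) == np.inf
        assert nm.zscore(1.0, [2.0, 2.0, 2.0]) == -np.inf
        assert nm.zscore(2.0, [2.0, 2.0, 2.0]) == 0.0

    def test_negative_iff_closer_than_null_mean(self):
        null = [1.0, 2.0, 3.0, 4.0]
        assert nm.zscore(1.0, null) < 0
        assert nm.zscore(4.0, null) > 0

    def test_too_few_finite_entries(self):
        with pytest.raises(ValueError):
            nm.zscore(1.0, [np.inf, 2.0])


class TestPFromZ:
    def test_symmetry_at_zero(self):
        assert nm.p_from_z(0.0) == 0.5

    @pytest.mark.parametrize("z,expected", [(-3.405, 0.00033), (-2.383, 0.00859)])
    def test_published_conversions(self, z, expected):
        assert round(nm.p_from_z(z), 5) == expected

    def test_complement_identity(self):
        for z in (-2.3, -0.7, 0.0, 1.1, 3.9):
            assert nm.p_from_z(z) + nm.p_from_z(-z) == pytest.approx(1.0)

    def test_sentinels(self):
        assert nm.p_from_z(-np.inf) == 0.0
        assert nm.p_from_z(np.inf) == 1.0

    def test_agrees_with_numerical_integration(self):
        dens = lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi)
        for z in np.linspace(-6, 6, 25):
            expected, _ = quad(dens, -np.inf, z)
            assert nm.p_from_z(z) == pytest.approx(expected, abs=1e-7)

    def test_monotone_in_z(self):
        zs = np.linspace(-6, 6, 50)
        ps = [nm.p_from_z(z) for z in zs]
        assert all(a < b for a, b in zip(ps, ps[1:]))


class TestBHAdjust:
    def test_step_up_example(self):
        adj, flags = nm.bh_adjust([0.001, 0.02, 0.9], alpha=0.25)
        assert flags == [True, True, False]
        assert adj == pytest.approx([0.003, 0.03, 0.9])

    def test_empty(self):
        assert nm.bh_adjust([], alpha=0.25) == ([], [])

    def test_equal_small_pvalues_all_flagged(self):
        adj, flags = nm.bh_adjust([0.1] * 5, alpha=0.25)
        assert all(flags)
        assert adj == pytest.approx([0.1] * 5)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(1)
        ps = rng.uniform(size=30)
        adj, _ = nm.bh_adjust(list(ps), alpha=0.25)
        assert all(a >= p for a, p in zip(adj, ps))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40),
           st.floats(min_value=0.01, max_value=0.5),
           st.floats(min_value=0.01, max_value=0.5))
    def test_flags_monotone_in_alpha(self, ps, a1, a2):
        lo, hi = sorted((a1, a2))
        _, f_lo = nm.bh_adjust(ps, alpha=lo)
        _, f_hi = nm.bh_adjust(ps, alpha=hi)
        assert all(not l or h for l, h in zip(f_lo, f_hi))


class TestProximityTable:
    def test_single_pair_invariants(self, path_graph):
        cfg = nm.ProximityConfig(n_random=50, master_seed=0)
        tab = nm.proximity_table(path_graph, {"q": {"A"}}, {"dz": {"C", "D"}}, cfg)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row["z"] == pytest.approx(
            (row["d_observed"] - row["mu_random"]) / row["sigma_random"])
        assert 0 <= row["p"] <= 1
        assert row["p_adjusted"] >= row["p"] - 1e-12
        assert bool(row["significant"]) == (row["p_adjusted"] <= cfg.fdr_alpha)

    def test_planted_disease_has_most_negative_z(self, default_scenario):
        sc = default_scenario
        cfg = nm.ProximityConfig(n_random=300, master_seed=7)
        tab = nm.proximity_table(sc.interactome, {"q": sc.query},
                                 sc.disease_genes, cfg)
        assert tab.iloc[0]["disease"] == "disease_00"
        assert tab.iloc[0]["z"] < 0

    def test_rows_sorted_by_z_ascending(self, default_scenario):
        sc = default_scenario
        cfg = nm.ProximityConfig(n_random=100, master_seed=1)
        tab = nm.proximity_table(sc.interactome, {"q": sc.query},
                                 sc.disease_genes, cfg)
        zs = tab["z"].to_numpy()
        assert (np.diff(zs) >= 0).all()

    def test_determinism(self, default_scenario):
        sc = default_scenario
        cfg = nm.ProximityConfig(n_random=100, master_seed=11)
        t1 = nm.proximity_table(sc.interactome, {"q": sc.query},
                                sc.disease_genes, cfg)
        t2 = nm.proximity_table(sc.interactome, {"q": sc.query},
                                sc.disease_genes, cfg)
        assert t1.equals(t2)

    def test_unmappable_disease_becomes_na_row(self, path_graph):
        cfg = nm.ProximityConfig(n_random=10, master_seed=0)
        tab = nm.proximity_table(path_graph, {"q": {"A"}},
                                 {"good": {"C"}, "bad": {"ZZ"}}, cfg)
        bad = tab[tab["disease"] == "bad"].iloc[0]
        assert np.isnan(bad["z"]) and bad["note"] != ""
        good = tab[tab["disease"] == "good"].iloc[0]
        assert np.isfinite(good["z"])
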