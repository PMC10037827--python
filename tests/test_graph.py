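import networkx as nx
import numpy as np
import pandas as pd
import pytest

import _oracles as orc
from symnetmap import DegenerateInputError, auc_over_sparsity, binarize_at_sparsity, sparsity_grid
from symnetmap.graph import (
    assortativity,
    auc_table,
    characteristic_path_length,
    clustering_coefficient,
    global_efficiency,
    hierarchy,
    hierarchy_exponent,
    local_efficiency,
    metric_curves,
    sigma,
    synchronization,
)


def _random_weight_matrix(rng, n):
    W = rng.standard_normal((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, np.nan)
    return W


class TestBinarize:
    def test_edge_count_arithmetic(self, rng):
        g = binarize_at_sparsity(_random_weight_matrix(rng, 10), 0.20)
        assert g.number_of_edges() == 9  # round(0.2 * 45)

    def test_full_sparsity_gives_complete_graph(self, rng):
        g = binarize_at_sparsity(_random_weight_matrix(rng, 8), 1.0)
        assert g.number_of_edges() == 28

    def test_matches_topk_brute_scan(self, rng):
        for _ in range(10):
            W = _random_weight_matrix(rng, 12)
            g = binarize_at_sparsity(W, 0.3)
            k = g.number_of_edges()
            W0 = np.nan_to_num(W, nan=-np.inf)
            assert {tuple(sorted(e)) for e in g.edges()} == orc.oracle_topk_edges(W0, k)

    def test_zero_edges_is_degenerate(self):
        W = np.zeros((4, 4))
        with pytest.raises(DegenerateInputError):
            binarize_at_sparsity(W, 0.01)

    def test_labels_follow_dataframe_index(self, rng):
        names = ["A", "B", "C", "D"]
        W = pd.DataFrame(_random_weight_matrix(rng, 4), index=names, columns=names)
        g = binarize_at_sparsity(W, 0.5)
        assert set(g.nodes()) == set(names)


class TestClosedForms:
    def test_triangle(self):
        k3 = nx.complete_graph(3)
        assert clustering_coefficient(k3) == 1.0
        assert characteristic_path_length(k3) == 1.0
        assert global_efficiency(k3) == 1.0

    def test_path_p3(self):
        p3 = nx.path_graph(3)
        assert characteristic_path_length(p3) == pytest.approx(4 / 3)
        assert global_efficiency(p3) == pytest.approx(5 / 6)
        assert synchronization(p3) == pytest.approx(1 / 3)

    def test_path_p4_assortativity(self):
        assert assortativity(nx.path_graph(4)) == pytest.approx(-0.5)

    def test_regular_graph_assortativity_undefined(self):
        assert np.isnan(assortativity(nx.complete_graph(6)))

    def test_complete_graph_synchronization_is_one(self):
        for n in (3, 5, 8):
            assert synchronization(nx.complete_graph(n)) == pytest.approx(1.0)

    def test_hierarchy_of_exact_power_law(self):
        k = np.array([2, 3, 4, 6, 9], float)
        c = k ** -0.7
        assert hierarchy_exponent(k, c) == pytest.approx(0.7, abs=1e-10)

    def test_hierarchy_undefined_for_single_degree(self):
        assert np.isnan(hierarchy(nx.complete_graph(5)))


class TestOracleEquivalence:
    def test_seeded_random_graphs_match_bruteforce(self):
        rng = np.random.default_rng(77)
        checked = 0
        for i in range(50):
            n = int(rng.integers(8, 26))
            p = float(rng.uniform(0.15, 0.6))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            A = orc.adjacency(g)
            assert clustering_coefficient(g) == pytest.approx(orc.oracle_cp(A), abs=1e-10)
            assert global_efficiency(g) == pytest.approx(orc.oracle_eglobal(A), abs=1e-10)
            assert local_efficiency(g) == pytest.approx(orc.oracle_elocal(A), abs=1e-10)
            lp = characteristic_path_length(g)
            olp = orc.oracle_lp(A)
            np.testing.assert_allclose(lp, olp, atol=1e-10)
            r, orr = assortativity(g), orc.oracle_assortativity(A)
            if np.isnan(orr):
                assert np.isnan(r)
            else:
                assert r == pytest.approx(orr, abs=1e-10)
            s, os_ = synchronization(g), orc.oracle_synchronization(A)
            np.testing.assert_allclose(s, os_, atol=1e-8)
            h, oh = hierarchy(g), orc.oracle_hierarchy(A)
            if np.isnan(oh):
                assert np.isnan(h)
            else:
                assert h == pytest.approx(oh, abs=1e-10)
            checked += 1
        assert checked == 50

    def test_isomorphism_invariance(self, rng):
        g = nx.gnp_random_graph(15, 0.3, seed=5)
        perm = rng.permutation(15)
        h = nx.relabel_nodes(g, {i: int(perm[i]) for i in range(15)})
        for fn in (clustering_coefficient, characteristic_path_length,
                   global_efficiency, local_efficiency, synchronization, hierarchy):
            a, b = fn(g), fn(h)
            np.testing.assert_allclose(a, b, atol=1e-12, equal_nan=True)


class TestSigma:
    def test_complete_graph_sigma_exactly_one(self):
        assert sigma(nx.complete_graph(8), n_null=10, rng_seed=1) == 1.0

    def test_reproducible_given_seed(self):
        g = nx.gnp_random_graph(20, 0.3, seed=3)
        assert sigma(g, n_null=20, rng_seed=9) == sigma(g, n_null=20, rng_seed=9)
        assert sigma(g, n_null=20, rng_seed=9) != sigma(g, n_null=20, rng_seed=10)

    def test_rewiring_preserves_degree_sequence(self):
        from symnetmap.graph import _rewire

        g = nx.gnp_random_graph(20, 0.3, seed=4)
        h = _rewire(g, np.random.default_rng(0), 10 * g.number_of_edges())
        assert sorted(d for _, d in h.degree()) == sorted(d for _, d in g.degree())
        assert h.number_of_edges() == g.number_of_edges()

    def test_erdos_renyi_sigma_near_one(self):
        """Random graphs are their own null model: sigma stays in a band
        around 1 across seeded replicates."""
        inside = 0
        reps = 40
        for i in range(reps):
            g = nx.gnp_random_graph(30, 0.3, seed=100 + i)
            s = sigma(g, n_null=50, rng_seed=i)
            inside += 0.8 <= s <= 1.2
        assert inside >= 0.95 * reps

    def test_small_world_ring_has_sigma_above_one(self):
        g = nx.watts_strogatz_graph(30, 4, 0.1, seed=2)
        assert sigma(g, n_null=100, rng_seed=7) > 1.0


class TestAUC:
    def test_constant_curve_rectangle(self):
        grid = sparsity_grid()
        assert auc_over_sparsity(np.full(31, 2.5), grid) == pytest.approx(0.75)

    def test_linear_curve_closed_form(self):
        grid = sparsity_grid()
        assert auc_over_sparsity(grid, grid) == pytest.approx(0.09)

    def test_matches_trapezoid_oracle(self, rng):
        grid = sparsity_grid()
        vals = rng.uniform(0, 1, 31)
        assert auc_over_sparsity(vals, grid) == pytest.approx(
            orc.oracle_trapezoid(vals, grid), abs=1e-12
        )

    def test_gaps_excluded_and_majority_gap_undefined(self, rng):
        grid = sparsity_grid()
        vals = rng.uniform(0, 1, 31)
        vals[3] = np.nan
        finite = np.isfinite(vals)
        expected = orc.oracle_trapezoid(vals[finite], grid[finite])
        assert auc_over_sparsity(vals, grid) == pytest.approx(expected, abs=1e-12)
        vals[:16] = np.nan
        assert np.isnan(auc_over_sparsity(vals, grid))

    def test_grid_has_31_points(self):
        assert len(sparsity_grid()) == 31
        assert sparsity_grid()[0] == pytest.approx(0.15)
        assert sparsity_grid()[-1] == pytest.approx(0.45)


class TestCurves:
    def test_monotone_density(self, rng):
        """On nested edge sets Eglobal never falls and Lp never rises as
        sparsity increases."""
        W = _random_weight_matrix(rng, 14)
        prev_eg, prev_lp, prev_conn = -np.inf, np.inf, False
        for s in (0.15, 0.25, 0.35, 0.45):
            g = binarize_at_sparsity(W, s)
            eg = global_efficiency(g)
            lp = characteristic_path_length(g)
            conn = nx.is_connected(g)
            assert eg >= prev_eg - 1e-12
            if conn and prev_conn:
                assert lp <= prev_lp + 1e-12
            prev_eg, prev_lp, prev_conn = eg, lp, conn

    def test_metric_curves_shape_and_bounds(self, rng):
        W = _random_weight_matrix(rng, 12)
        curves = metric_curves(W, n_null=10, rng_seed=0)
        assert curves.shape == (31, 8)
        assert ((curves["Cp"] >= 0) & (curves["Cp"] <= 1)).all()
        assert ((curves["Eglobal"] >= 0) & (curves["Eglobal"] <= 1)).all()
        assert ((curves["Elocal"] >= 0) & (curves["Elocal"] <= 1)).all()
        assert (curves["Lp"].dropna() >= 1).all()
        aucs = auc_table({"s1": curves})
        assert aucs.loc["s1", "Cp__coverage"] == 1.0
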