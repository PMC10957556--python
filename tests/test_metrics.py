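"""Weighted graph metrics against hand-computed and brute-force oracles."""

import itertools
import warnings

import numpy as np
import pytest

import fcnet as f
from conftest import graph_from_edges, net_from


class TestDegreeStrength:
    def test_triangle(self, triangle):
        k, s = f.degree_strength(triangle)
        assert np.array_equal(k, [2, 2, 2]) and np.allclose(s, 2)

    def test_isolated_node(self):
        w = graph_from_edges(3, [(0, 1)])
        k, s = f.degree_strength(w)
        assert k[2] == 0 and s[2] == 0

    def test_handshake_lemma_on_thresholded_net(self, signed_synthetic_z):
        net = f.proportional_threshold(signed_synthetic_z, 0.16)
        k, _ = f.degree_strength(net)
        assert k.sum() == 2 * 283
        assert k.mean() == pytest.approx(2 * 283 / 60)


class TestClusteringTransitivity:
    def test_unit_triangle(self, triangle):
        cc, t = f.clustering_transitivity(triangle)
        assert np.allclose(cc, 1.0) and t == pytest.approx(1.0)

    def test_star_has_no_triangles(self, star5):
        cc, t = f.clustering_transitivity(star5)
        assert np.allclose(cc, 0.0) and t == 0.0

    def test_onnela_geometric_mean_hand_value(self):
        # CC(a) = (w_ab w_ac w_bc)^(1/3) with w normalized by max = 1
        w = graph_from_edges(4, [(0, 1), (0, 2), (1, 2), (2, 3)],
                             {(0, 1): 1.0, (0, 2): 1.0, (1, 2): 0.5, (2, 3): 1.0})
        cc, _ = f.clustering_transitivity(w)
        assert cc[0] == pytest.approx(0.5 ** (1 / 3), abs=1e-12)

    def test_uniform_weights_match_binary(self):
        rng = np.random.default_rng(0)
        a = (rng.random((12, 12)) < 0.4).astype(float)
        a = np.triu(a, 1)
        a = a + a.T
        cc_w, t_w = f.clustering_transitivity(0.7 * a)
        import networkx as nx

        g = nx.from_numpy_array(a)
        assert t_w == pytest.approx(nx.transitivity(g), abs=1e-10)
        cc_bin = nx.clustering(g)
        assert np.allclose(cc_w, [cc_bin[i] for i in range(12)], atol=1e-10)


class TestPathMetrics:
    def test_unit_path_hand_values(self, path3):
        cpl, eff = f.path_metrics(path3)
        assert cpl == pytest.approx(4 / 3, abs=1e-12)
        assert eff == pytest.approx(5 / 6, abs=1e-12)

    def test_complete_unit_graph(self):
        w = 1 - np.eye(6)
        cpl, eff = f.path_metrics(w)
        assert cpl == pytest.approx(1.0) and eff == pytest.approx(1.0)

    def test_weights_shorten_paths(self):
        # heavy indirect route beats a weak direct edge: d(0,2)=1/2+1/2 < 1/0.4
        w = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)],
                             {(0, 1): 2.0, (1, 2): 2.0, (0, 2): 0.4})
        cpl, _ = f.path_metrics(w)
        assert cpl == pytest.approx((0.5 + 0.5 + 1.0) / 3, abs=1e-12)

    def test_disconnected_pairs_excluded_from_cpl(self):
        w = graph_from_edges(4, [(0, 1), (2, 3)])
        cpl, eff = f.path_metrics(w)
        assert cpl == pytest.approx(1.0)  # only the two connected pairs
        assert eff == pytest.approx(2 / 6)

    def test_empty_graph_flagged(self):
        with pytest.warns(UserWarning, match="disconnected"):
            cpl, eff = f.path_metrics(np.zeros((3, 3)))
        assert np.isnan(cpl) and eff == 0.0


class TestLocalEfficiency:
    def test_triangle_and_star(self, triangle, star5):
        assert np.allclose(f.local_efficiency(triangle), 1.0)
        assert np.allclose(f.local_efficiency(star5), 0.0)

    def test_matches_brute_force_neighbor_subgraph_oracle(self):
        rng = np.random.default_rng(4)
        w = rng.random((5, 5)) * (rng.random((5, 5)) < 0.7)
        w = np.triu(w, 1)
        w = w + w.T
        wn = w / w.max()

        def oracle(i):
            nb = np.flatnonzero(wn[i] > 0)
            if nb.size < 2:
                return 0.0
            # exhaustive shortest paths over all simple paths in the subgraph
            best = {}
            for a_idx, b_idx in itertools.combinations(range(nb.size), 2):
                dists = []
                for perm_len in range(2, nb.size + 1):
                    for perm in itertools.permutations(range(nb.size), perm_len):
                        if perm[0] != a_idx or perm[-1] != b_idx:
                            continue
                        legs = [
                            wn[nb[u], nb[v]] for u, v in zip(perm, perm[1:])
                        ]
                        if all(x > 0 for x in legs):
                            dists.append(sum(1 / x for x in legs))
                best[(a_idx, b_idx)] = min(dists) if dists else np.inf
            vals = [1 / d if np.isfinite(d) else 0.0 for d in best.values()]
            return float(np.mean(vals))

        eloc = f.local_efficiency(w)
        for i in range(5):
            assert eloc[i] == pytest.approx(oracle(i), abs=1e-12)


class TestAssortativity:
    def test_star_is_maximally_disassortative(self, star5):
        assert f.assortativity(star5, "degree") == pytest.approx(-1.0)

    def test_regular_graph_undefined_not_zero(self, triangle):
        other = graph_from_edges(6, [(3, 4), (3, 5), (4, 5)])
        w = triangle.copy()
        two_triangles = np.zeros((6, 6))
        two_triangles[:3, :3] = w
        two_triangles += other
        with pytest.warns(UserWarning, match="zero endpoint variance"):
            r = f.assortativity(two_triangles, "degree")
        assert np.isnan(r)

    def test_two_joined_hubs_with_leaves_are_disassortative(self):
        edges = [(0, 1)] + [(0, i) for i in range(2, 6)] + [(1, i) for i in range(6, 10)]
        w = graph_from_edges(10, edges)
        assert f.assortativity(w, "degree") < 0

    def test_matches_direct_edge_list_correlation(self):
        rng = np.random.default_rng(8)
        w = (rng.random((15, 15)) < 0.3) * rng.random((15, 15))
        w = np.triu(w, 1)
        w = w + w.T
        k, s = f.degree_strength(w)
        iu, ju = np.nonzero(np.triu(w, 1))
        for mode, x in (("degree", k.astype(float)), ("strength", s)):
            a = np.concatenate([x[iu], x[ju]])
            b = np.concatenate([x[ju], x[iu]])
            assert f.assortativity(w, mode) == pytest.approx(
                np.corrcoef(a, b)[0, 1], abs=1e-12
            )


class TestParticipation:
    def test_formula_cases(self):
        # all edges within own module -> 0
        w = graph_from_edges(4, [(0, 1), (2, 3)])
        p = f.participation_coefficient(w, [1, 1, 2, 2])
        assert np.allclose(p, 0.0)
        # split equally across 2 modules -> 0.5
        w = graph_from_edges(3, [(0, 1), (0, 2)])
        p = f.participation_coefficient(w, [1, 1, 2])
        assert p[0] == pytest.approx(0.5)
        # equal thirds across 3 modules -> 2/3
        w = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        p = f.participation_coefficient(w, [1, 1, 2, 3])
        assert p[0] == pytest.approx(2 / 3)

    def test_isolated_node_and_length_mismatch(self):
        w = graph_from_edges(3, [(0, 1)])
        assert f.participation_coefficient(w, [1, 1, 2])[2] == 0.0
        with pytest.raises(ValueError, match="partition length"):
            f.participation_coefficient(w, [1, 1])

    def test_bounded_by_one_minus_inverse_module_count(self):
        rng = np.random.default_rng(9)
        w = (rng.random((20, 20)) < 0.3).astype(float)
        w = np.triu(w, 1)
        w = w + w.T
        labels = rng.integers(1, 5, size=20)
        m = np.unique(labels).size
        p = f.participation_coefficient(w, labels)
        assert np.all(p <= 1 - 1 / m + 1e-12) and np.all(p >= 0)


class TestSmallWorld:
    def test_self_ensemble_gives_unity(self, two_cliques_bridge):
        sw = f.small_world(two_cliques_bridge, [two_cliques_bridge])
        assert sw.gamma == pytest.approx(1.0) and sw.lam == pytest.approx(1.0)
        assert sw.swc == pytest.approx(1.0)

    def test_er_graph_swc_near_one(self):
        import networkx as nx

        swcs = []
        for rep in range(10):
            w = nx.to_numpy_array(nx.gnm_random_graph(60, 283, seed=rep))
            ens = f.null_ensemble(w, m=8, seed=rep).matrices
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                swcs.append(f.small_world(w, ens).swc)
        assert abs(np.mean(swcs) - 1.0) < 0.1

    def test_watts_strogatz_is_small_world(self):
        import networkx as nx

        w = nx.to_numpy_array(nx.watts_strogatz_graph(60, 10, 0.1, seed=1))
        ens = f.null_ensemble(w, m=10, seed=5).matrices
        latt = f.lattice_reference(net_from(w), seed=2)
        sw = f.small_world(w, ens, latt)
        assert sw.swc > 1.0
        assert np.isfinite(sw.swm)


class TestRichClub:
    def test_complete_graph_phi_is_one(self):
        w = 1 - np.eye(6)
        curve = f.rich_club(w)
        defined = np.isfinite(curve.phi)
        assert defined.any() and np.allclose(curve.phi[defined], 1.0)

    def test_star_undefined_beyond_k1(self, star5):
        curve = f.rich_club(star5)
        assert np.all(np.isnan(curve.phi[curve.k_grid > 1]))

    def test_weighted_core_matches_enumeration_oracle(self):
        # 3-node strongly weighted core inside a 6-node graph
        weights = {(0, 1): 5.0, (0, 2): 4.0, (1, 2): 4.5,
                   (0, 3): 1.0, (1, 4): 1.0, (2, 5): 1.0, (3, 4): 0.5}
        w = graph_from_edges(6, list(weights), weights)
        k, _ = f.degree_strength(w)
        curve = f.rich_club(w)
        kk = 2
        nodes = np.flatnonzero(k > kk)  # core 0,1,2
        assert set(nodes) == {0, 1, 2}
        club_w = 5.0 + 4.0 + 4.5
        top3 = sum(sorted(weights.values(), reverse=True)[:3])
        expected = club_w / top3
        assert curve.phi[curve.k_grid == kk][0] == pytest.approx(expected, abs=1e-12)

    def test_er_phi_norm_near_one_for_small_k(self):
        vals = []
        for rep in range(20):
            r = np.random.default_rng(100 + rep)
            a = np.triu(r.random((60, 60)) < 0.16, 1).astype(float)
            w = np.where(a > 0, 0.5 + 0.5 * r.random((60, 60)), 0.0)
            w = w + w.T
            ens = f.null_ensemble(w, m=10, seed=rep).matrices
            curve = f.rich_club(w, ens)
            vals.extend(x for x in curve.phi_norm[:5] if np.isfinite(x))
        vals = np.array(vals)
        assert np.mean((vals >= 0.9) & (vals <= 1.1)) >= 0.95


class TestPermutationInvariance:
    def test_global_metrics_invariant_under_relabeling(self):
        rng = np.random.default_rng(12)
        w = (rng.random((15, 15)) < 0.3) * rng.random((15, 15))
        w = np.triu(w, 1)
        w = w + w.T
        perm = rng.permutation(15)
        wp = w[np.ix_(perm, perm)]
        _, t1 = f.clustering_transitivity(w)
        _, t2 = f.clustering_transitivity(wp)
        assert t1 == pytest.approx(t2, abs=1e-12)
        assert f.path_metrics(w)[0] == pytest.approx(f.path_metrics(wp)[0], abs=1e-12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert f.assortativity(w) == pytest.approx(f.assortativity(wp), abs=1e-12)
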