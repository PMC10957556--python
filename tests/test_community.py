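"""Modularity, Louvain, consensus clustering: closed forms and brute force."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

import fcnet as f
from fcnet.community import module_census
from conftest import graph_from_edges


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def labels_of(partition, n):
    lab = np.empty(n, dtype=int)
    for ci, block in enumerate(partition):
        lab[block] = ci + 1
    return lab


class TestModularityValue:
    def test_single_module_is_zero(self, two_cliques_bridge):
        q = f.modularity_value(two_cliques_bridge, np.ones(8, dtype=int))
        assert q == pytest.approx(0.0, abs=1e-15)

    def test_two_clique_hand_value(self, two_cliques_bridge):
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        q = f.modularity_value(two_cliques_bridge, labels)
        assert q == pytest.approx(2 * (6 / 13 - (13 / 26) ** 2), abs=1e-12)

    def test_singletons_give_negative_q(self, two_cliques_bridge):
        q = f.modularity_value(two_cliques_bridge, np.arange(1, 9))
        k = two_cliques_bridge.sum(1)
        assert q == pytest.approx(-np.sum((k / k.sum()) ** 2), abs=1e-12)

    def test_matches_networkx_on_random_graph(self):
        import networkx as nx

        rng = np.random.default_rng(0)
        w = (rng.random((12, 12)) < 0.4) * rng.random((12, 12))
        w = np.triu(w, 1)
        w = w + w.T
        labels = rng.integers(1, 4, size=12)
        g = nx.from_numpy_array(w)
        comms = [set(np.flatnonzero(labels == c)) for c in np.unique(labels)]
        expected = nx.community.modularity(g, comms, weight="weight")
        assert f.modularity_value(w, labels) == pytest.approx(expected, abs=1e-10)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            f.modularity_value(np.zeros((3, 3)), np.ones(3, dtype=int))


class TestLouvain:
    def test_two_disjoint_cliques_found_for_any_seed(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        w = graph_from_edges(8, edges)
        for seed in range(5):
            p = f.louvain_once(w, seed=seed)
            assert p.n_modules == 2
            assert len(set(p.affiliation[:4])) == 1 and len(set(p.affiliation[4:])) == 1

    def test_attains_exhaustive_optimum_on_bridge_graph(self, two_cliques_bridge):
        best_q = max(
            f.modularity_value(two_cliques_bridge, labels_of(part, 8))
            for part in set_partitions(list(range(8)))
        )
        p = f.louvain_once(two_cliques_bridge, seed=0)
        assert best_q == pytest.approx(2 * (6 / 13 - (13 / 26) ** 2), abs=1e-12)
        assert p.q == pytest.approx(best_q, abs=1e-12)

    def test_deterministic_given_seed(self, signed_synthetic_z):
        net = f.proportional_threshold(signed_synthetic_z, 0.16)
        p1, p2 = f.louvain_once(net, seed=5), f.louvain_once(net, seed=5)
        assert np.array_equal(p1.affiliation, p2.affiliation) and p1.q == p2.q

    def test_q_at_least_trivial_partition(self, signed_synthetic_z):
        net = f.proportional_threshold(signed_synthetic_z, 0.16)
        assert f.louvain_once(net, seed=1).q >= 0.0

    def test_q_consistent_with_modularity_value(self, signed_synthetic_z):
        net = f.proportional_threshold(signed_synthetic_z, 0.16)
        p = f.louvain_once(net, seed=2)
        assert p.q == pytest.approx(
            f.modularity_value(net, p.affiliation), abs=1e-10
        )

    def test_labels_canonical_contiguous_by_size(self, signed_synthetic_z):
        net = f.proportional_threshold(signed_synthetic_z, 0.16)
        lab = f.louvain_once(net, seed=3).affiliation
        uniq = np.unique(lab)
        assert uniq[0] == 1 and np.array_equal(uniq, np.arange(1, uniq.size + 1))
        sizes = [(lab == c).sum() for c in uniq]
        assert sizes == sorted(sizes, reverse=True)


class TestConsensus:
    def test_unambiguous_graph_consensus_equals_runs(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        w = graph_from_edges(8, edges)
        res = f.consensus_partition(w, n_iter=10, seed=0)
        assert res.n_modules == 2 and res.module_sizes == [4, 4]
        assert res.q_summary == pytest.approx(res.final_partition.q, abs=1e-12)

    def test_single_iteration_equals_single_run(self, signed_synthetic_z):
        net = f.proportional_threshold(signed_synthetic_z, 0.16)
        res = f.consensus_partition(net, n_iter=1, seed=4)
        assert len(res.q_runs) == 1
        assert res.q_summary == res.q_runs[0]

    def test_planted_partition_recovery(self):
        spec = f.CohortSpec(groups=("g",), n_per_group=3, rho_within=0.5,
                            rho_between=0.05, seed=21)
        for subj in f.make_cohort(spec):
            c = f.correlation_matrix(
                f.SubjectTimeseries(subj.subject_id, subj.timeseries)
            )
            net = f.proportional_threshold(c, 0.16)
            res = f.consensus_partition(net, n_iter=40, seed=1)
            ari = adjusted_rand_score(
                subj.planted_partition, res.final_partition.affiliation
            )
            assert ari >= 0.9

    def test_consensus_does_not_degrade_quality(self, signed_synthetic_z):
        net = f.proportional_threshold(signed_synthetic_z, 0.16)
        res = f.consensus_partition(net, n_iter=30, seed=6)
        assert res.final_partition.q >= np.median(res.q_runs) - 0.02

    def test_q_always_in_valid_range(self, signed_synthetic_z):
        for d in (0.06, 0.16, 0.32):
            net = f.proportional_threshold(signed_synthetic_z, d)
            res = f.consensus_partition(net, n_iter=10, seed=7)
            assert -0.5 <= res.final_partition.q <= 1.0
            assert np.all((res.q_runs >= -0.5) & (res.q_runs <= 1.0))


class TestModuleCensus:
    def test_single_subject_summary(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        edges += [(i, j) for i in range(4, 8) for j in range(i + 1, 8)]
        w = graph_from_edges(8, edges)
        res = f.consensus_partition(w, n_iter=5, seed=0)
        df = module_census({"s1": res})
        assert df.loc[0, "n_modules"] == 2 and df.loc[0, "largest_module"] == 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no consensus results"):
            module_census({})

    def test_lower_between_coupling_gives_no_more_modules(self):
        # group a (rho_between=0.05) should not show more modules than
        # group b (0.15); scaled-down regeneration check
        wins = 0
        reps = 6
        for rep in range(reps):
            spec = f.CohortSpec(groups=("a", "b"), n_per_group=3, rho_within=0.5,
                                rho_between={"a": 0.05, "b": 0.15}, seed=300 + rep)
            counts = {"a": [], "b": []}
            for subj in f.make_cohort(spec):
                c = f.correlation_matrix(
                    f.SubjectTimeseries(subj.subject_id, subj.timeseries)
                )
                net = f.proportional_threshold(c, 0.16)
                res = f.consensus_partition(net, n_iter=20, seed=rep)
                counts[subj.group].append(res.n_modules)
            wins += np.median(counts["a"]) <= np.median(counts["b"])
        assert wins >= int(0.8 * reps)
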