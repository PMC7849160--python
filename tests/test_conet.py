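import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stabilome import conet
from stabilome.functional_classes import (
    BROAD_METABOLIC,
    CELLULAR_PROCESSES,
    ENVIRONMENTAL_INFORMATION_PROCESSING,
    SPECIALIZED_METABOLIC,
    UNMAPPED,
    functional_class_of,
)
from stabilome.io_model import CountTable

from .oracles import (
    bh_adjust_bruteforce,
    modularity_bruteforce,
    spearman_bruteforce,
    topology_bruteforce,
)


def table_from(arr):
    arr = np.asarray(arr, dtype=float)
    return CountTable(pd.DataFrame(
        arr, index=[f"f{i}" for i in range(arr.shape[0])],
        columns=[f"s{j}" for j in range(arr.shape[1])],
    ))


class TestCorrelateAllPairs:
    def test_worked_rank_example(self):
        t = table_from([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5]])
        edges = conet.correlate_all_pairs(t)
        assert edges.loc[0, "r"] == pytest.approx(0.8)

    def test_monotone_map_gives_perfect_correlation(self):
        x = np.array([1, 3, 7, 20, 50], dtype=float)
        t = table_from([x, x**2 + 1])
        edges = conet.correlate_all_pairs(t)
        assert edges.loc[0, "r"] == pytest.approx(1.0)

    def test_matches_bruteforce_rank_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            arr = rng.integers(0, 30, (8, 12)).astype(float) + rng.random((8, 12))
            t = table_from(arr)
            edges = conet.correlate_all_pairs(t).set_index(["feature_a", "feature_b"])
            for i, j in itertools.combinations(range(8), 2):
                expect = spearman_bruteforce(arr[i], arr[j])
                assert edges.loc[(f"f{i}", f"f{j}"), "r"] == pytest.approx(expect, abs=1e-12)

    def test_bh_worked_example_and_properties(self):
        pvals = [0.01, 0.02, 0.03, 0.04]
        expect = bh_adjust_bruteforce(pvals)
        assert expect == pytest.approx([0.04, 0.04, 0.04, 0.04])
        rng = np.random.default_rng(1)
        arr = rng.random((7, 10))
        edges = conet.correlate_all_pairs(table_from(arr))
        oracle = bh_adjust_bruteforce(edges["p"].tolist())
        assert edges["q"].to_numpy() == pytest.approx(np.array(oracle), abs=1e-12)
        assert (edges["q"] >= edges["p"] - 1e-15).all()
        assert (edges["q"] <= 1.0).all()

    def test_constant_feature_pairs_excluded_from_bh_family(self):
        arr = np.vstack([np.ones(10), np.random.default_rng(2).random((3, 10))])
        edges = conet.correlate_all_pairs(table_from(arr))
        und = edges[edges["feature_a"] == "f0"]
        assert und["r"].isna().all() and und["q"].isna().all()
        assert edges[edges["feature_a"] != "f0"]["q"].notna().all()


class TestBuildNetwork:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p", "q", "sign"])

    def test_threshold_logic(self):
        edges = self.frame([
            ("a", "b", 0.80, 0.001, 0.005, 1.0),   # retained positive
            ("a", "c", -0.90, 0.0001, 0.001, -1.0),  # retained negative (|r| rule)
            ("b", "c", 0.80, 0.001, 0.02, 1.0),    # fails q
            ("c", "d", 0.70, 0.001, 0.001, 1.0),   # fails r
        ])
        net = conet.build_network(edges)
        assert set(net.edges) == {("a", "b"), ("a", "c")}
        assert net["a"]["c"]["sign"] == -1

    def test_empty_result_is_not_an_error(self):
        net = conet.build_network(self.frame([("a", "b", 0.1, 0.9, 0.9, 1.0)]))
        assert net.number_of_nodes() == 0


class TestTopology:
    def test_triangle_graph(self):
        g = nx.complete_graph(3)
        s = conet.topology_summary(g, seed=0)
        assert (s.avg_k, s.avg_cc, s.apd, s.graph_density) == (2.0, 1.0, 1.0, 1.0)

    def test_path_graph_hand_enumeration(self):
        g = nx.path_graph(3)
        s = conet.topology_summary(g, seed=0)
        assert s.avg_cc == 0.0
        assert s.apd == pytest.approx(4 / 3)

    def test_gd_equals_avgk_over_n_minus_one(self):
        g = nx.gnm_random_graph(30, 80, seed=1)
        s = conet.topology_summary(g, seed=0)
        assert s.graph_density == pytest.approx(s.avg_k / (s.n_nodes - 1), abs=1e-12)

    def test_matches_bruteforce_on_random_graphs(self):
        for seed in range(5):
            g = nx.gnm_random_graph(40, 90, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            s = conet.topology_summary(g, seed=0)
            oracle = topology_bruteforce(list(g.edges))
            assert s.avg_k == pytest.approx(oracle["avg_k"], abs=1e-12)
            assert s.avg_cc == pytest.approx(oracle["avg_cc"], abs=1e-12)
            assert s.apd == pytest.approx(oracle["apd"], abs=1e-12)
            assert s.graph_density == pytest.approx(oracle["graph_density"], abs=1e-12)


class TestModules:
    def test_two_disjoint_triangles_modularity_half(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        partition, m = conet.partition_modules(g, seed=0)
        assert m == pytest.approx(0.5)
        assert len(set(partition.values())) == 2
        assert modularity_bruteforce(list(g.edges), partition) == pytest.approx(0.5)

    def test_complete_graph_has_no_structure(self):
        _, m = conet.partition_modules(nx.complete_graph(8), seed=0)
        assert m == pytest.approx(0.0, abs=1e-9)

    def test_planted_partition_recovery(self):
        g = nx.planted_partition_graph(4, 12, 0.9, 0.02, seed=3)
        partition, m = conet.partition_modules(g, seed=1)
        # adjusted agreement with the planted blocks
        from sklearn.metrics import adjusted_rand_score

        truth = [v // 12 for v in sorted(g.nodes)]
        found = [partition[v] for v in sorted(g.nodes)]
        assert adjusted_rand_score(truth, found) > 0.9
        assert m > 0.5

    def test_deterministic_for_fixed_seed(self):
        g = nx.gnm_random_graph(40, 120, seed=2)
        p1, m1 = conet.partition_modules(g, seed=5)
        p2, m2 = conet.partition_modules(g, seed=5)
        assert p1 == p2 and m1 == m2


class TestRandomEnsemble:
    def test_fixed_m_identities(self):
        g = nx.gnm_random_graph(100, 495, seed=0)
        ens = conet.random_ensemble_summary(g, n_draws=10, seed=1)
        assert ens.loc["avg_k", "mean"] == pytest.approx(2 * 495 / 100)
        assert ens.loc["avg_k", "sd"] == pytest.approx(0.0, abs=1e-12)
        assert ens.loc["graph_density", "mean"] == pytest.approx(0.1)

    def test_clustering_matches_er_expectation(self):
        g = nx.gnm_random_graph(60, 300, seed=4)
        ens = conet.random_ensemble_summary(g, n_draws=100, seed=2)
        # E[avgCC] of G(n,m) ~ 2m / (n (n-1)) = edge probability
        expect = 2 * 300 / (60 * 59)
        assert abs(ens.loc["avg_cc", "mean"] - expect) < 3 * ens.loc["avg_cc", "sd"] / 10 + 0.02

    def test_planted_modular_graph_beats_its_ensemble(self):
        wins = 0
        for seed in range(10):
            g = nx.planted_partition_graph(4, 10, 0.8, 0.03, seed=seed)
            g.remove_nodes_from(list(nx.isolates(g)))
            _, m = conet.partition_modules(g, seed=seed)
            ens = conet.random_ensemble_summary(g, n_draws=20, seed=seed)
            wins += m > ens.loc["modularity", "mean"]
        assert wins == 10

    def test_minimum_draw_count_enforced(self):
        with pytest.raises(ValueError, match=">= 10"):
            conet.random_ensemble_summary(nx.complete_graph(4), n_draws=3, seed=0)


class TestNodeRoles:
    def star_in_module(self):
        g = nx.Graph()
        g.add_edges_from([("hub", "a"), ("hub", "b"), ("hub", "c")])
        partition = {"hub": 0, "a": 0, "b": 0, "c": 0}
        return g, partition

    def test_hand_computed_zi(self):
        g, partition = self.star_in_module()
        roles = conet.node_roles(g, partition)
        assert roles.loc["hub", "zi"] == pytest.approx(1.7320508, abs=1e-6)

    def test_pi_worked_cases(self):
        g = nx.Graph()
        g.add_edges_from([("v", "a1"), ("v", "a2"), ("v", "b1"), ("v", "b2")])
        partition = {"v": 0, "a1": 1, "a2": 1, "b1": 2, "b2": 2}
        roles = conet.node_roles(g, partition)
        assert roles.loc["v", "pi"] == pytest.approx(0.5)
        g2, p2 = self.star_in_module()
        assert conet.node_roles(g2, p2).loc["hub", "pi"] == 0.0

    def test_role_taxonomy_exhaustive_on_grid(self):
        for zi in (-1.0, 0.0, 2.5, 2.6, 4.0):
            for pi in (0.0, 0.3, 0.62, 0.63, 0.9):
                if zi > 2.5:
                    expect = "network_hub" if pi > 0.62 else "module_hub"
                else:
                    expect = "connector" if pi > 0.62 else "peripheral"
                assert conet.role_from_zi_pi(zi, pi) == expect

    def test_partition_must_cover_nodes(self):
        g, partition = self.star_in_module()
        del partition["c"]
        with pytest.raises(ValueError, match="cover"):
            conet.node_roles(g, partition)


class TestFunctionalClasses:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("Nitrogen metabolism", SPECIALIZED_METABOLIC),
            ("nitrogen metabolism", SPECIALIZED_METABOLIC),
            ("Glycolysis/Gluconeogenesis", BROAD_METABOLIC),
            ("Ion channels", ENVIRONMENTAL_INFORMATION_PROCESSING),
            ("completely made-up pathway", UNMAPPED),
        ],
    )
    def test_vocabulary_lookup(self, name, expected):
        assert functional_class_of(name) == expected


class TestEdgeSignSummary:
    def test_aggregate_counting(self):
        g = nx.Graph()
        g.add_edge("Nitrogen metabolism", "TCA cycle", sign=-1)
        g.add_edge("Ion channels", "Flagellar assembly", sign=1)
        g.add_edge("Nitrogen metabolism", "Ion channels", sign=1)
        classes = {
            "Nitrogen metabolism": SPECIALIZED_METABOLIC,
            "TCA cycle": BROAD_METABOLIC,
            "Ion channels": ENVIRONMENTAL_INFORMATION_PROCESSING,
            "Flagellar assembly": CELLULAR_PROCESSES,
        }
        out = conet.edge_sign_summary(g, classes)
        assert out.loc["metabolic"].tolist() == [0, 1]
        assert out.loc["environmental_responses"].tolist() == [1, 0]
        assert out.loc["cross_aggregate"].tolist() == [1, 0]

    def test_planted_opposite_trends_make_cross_class_negative_edges(self):
        from stabilome.conet import build_network, correlate_all_pairs
        from stabilome.functional_classes import class_map
        from stabilome.synth import (
            DilutionScenario,
            FunctionalScenario,
            simulate_dilution_design,
            simulate_functional_profiles,
        )

        _, _, meta = simulate_dilution_design(DilutionScenario(seed=2))
        ft = simulate_functional_profiles(FunctionalScenario(seed=2), meta)
        net = build_network(correlate_all_pairs(ft))
        classes = class_map(ft.features)
        negs = [
            (u, v) for u, v, d in net.edges(data=True)
            if d["sign"] < 0
            and {classes[u], classes[v]} <= {SPECIALIZED_METABOLIC, BROAD_METABOLIC}
        ]
        crossing = [
            e for e in negs
            if {classes[e[0]], classes[e[1]]} == {SPECIALIZED_METABOLIC, BROAD_METABOLIC}
        ]
        assert negs, "expected negative metabolic edges under opposite trends"
        assert len(crossing) / len(negs) > 0.5
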