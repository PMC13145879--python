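"""ANOVA/Tukey/CI statistics, confusion metrics and the similarity
network."""

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import anova_reference

from leafcode import network as net
from leafcode import stats
from leafcode.stats import ConfusionMatrix

CM2 = ConfusionMatrix(["c1", "c2"], np.array([[9, 1], [2, 8]]))


class TestPerClassMetrics:
    def test_hand_computed_two_class(self):
        per = stats.per_class_metrics(CM2).set_index("class")
        assert per.loc["c1", "precision"] == pytest.approx(9 / 11)
        assert per.loc["c1", "recall"] == pytest.approx(0.9)
        assert per.loc["c1", "f"] == pytest.approx(0.8571, abs=1e-4)

    def test_diagonal_is_perfect(self):
        cm = ConfusionMatrix(["a", "b", "c"], np.diag([5, 3, 2]))
        per = stats.per_class_metrics(cm)
        assert (per[["precision", "recall", "f"]] == 1.0).all().all()

    def test_never_predicted_class_gets_zero_precision(self):
        cm = ConfusionMatrix(["a", "b"], np.array([[5, 0], [3, 0]]))
        per = stats.per_class_metrics(cm).set_index("class")
        assert per.loc["b", "precision"] == 0.0
        assert per.loc["b", "recall"] == 0.0


class TestSummaryMetrics:
    def test_accuracy_and_weighted_f(self):
        with pytest.warns(UserWarning, match="ROC"):
            out = stats.summary_metrics(CM2)
        assert out["accuracy"] == pytest.approx(0.85)
        # support-weighted mean of 0.8571 and 0.8421
        assert out["weighted_f"] == pytest.approx(0.8497, abs=1e-4)

    def test_perfect_scores_give_auc_one(self):
        y = np.array(["c1"] * 10 + ["c2"] * 10)
        proba = np.zeros((20, 2))
        proba[:10, 0] = 1.0
        proba[10:, 1] = 1.0
        out = stats.summary_metrics(CM2, y_true=y, proba=proba)
        assert out["roc_auc"] == 1.0


GROUPS = [np.array([1.0, 2, 3]), np.array([2.0, 3, 4]), np.array([3.0, 4, 5])]


class TestAnova:
    def test_hand_computed_example(self):
        res = stats.anova_oneway(GROUPS)
        assert res.F == pytest.approx(3.0, abs=1e-9)
        assert res.p == pytest.approx(0.125, abs=1e-9)
        assert res.eta2 == pytest.approx(0.5, abs=1e-9)
        assert res.omega2 == pytest.approx(4 / 13, abs=1e-4)

    def test_identical_groups(self):
        res = stats.anova_oneway([np.ones(4), np.ones(4)])
        assert res.F == 0.0
        assert res.p == 1.0
        assert res.eta2 == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_two_pass(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(rng.normal(), 1, rng.integers(3, 9))
                  for _ in range(rng.integers(2, 6))]
        res = stats.anova_oneway(groups)
        f_ref, ssb, ssw, _, _ = anova_reference([list(g) for g in groups])
        assert res.F == pytest.approx(f_ref, abs=1e-9)
        assert res.ss_between == pytest.approx(ssb, abs=1e-9)
        assert res.ss_within == pytest.approx(ssw, abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_effect_sizes_ordered_and_bounded(self, seed):
        rng = np.random.default_rng(100 + seed)
        groups = [rng.normal(k * 0.2, 1, 6) for k in range(3)]
        res = stats.anova_oneway(groups)
        assert 0 <= res.omega2 <= res.eta2 <= 1

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            stats.anova_oneway([np.array([1.0]), np.array([2.0, 3.0])])


class TestTukey:
    def test_hand_computed_pair(self):
        res = stats.tukey_hsd({"A": GROUPS[0], "B": GROUPS[1], "C": GROUPS[2]})
        ac = res[(res.group_1 == "A") & (res.group_2 == "C")].iloc[0]
        assert ac["mean_diff"] == pytest.approx(-2.0)
        assert ac["q"] == pytest.approx(2 / np.sqrt(1 / 3), abs=1e-6)

    def test_identical_groups_p_one(self):
        res = stats.tukey_hsd({"A": np.ones(4), "B": np.ones(4)})
        assert (res["mean_diff"] == 0).all()
        assert (res["p_adj"] == 1.0).all()

    def test_cross_check_against_scipy(self):
        from scipy.stats import tukey_hsd as scipy_tukey

        rng = np.random.default_rng(5)
        groups = {c: rng.normal(i, 1, 8) for i, c in enumerate("ABC")}
        ours = stats.tukey_hsd(groups)
        ref = scipy_tukey(*groups.values())
        pairs = {("A", "B"): (0, 1), ("A", "C"): (0, 2), ("B", "C"): (1, 2)}
        for _, row in ours.iterrows():
            i, j = pairs[(row.group_1, row.group_2)]
            assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-6)

    def test_p_monotone_in_mean_difference(self):
        base = np.array([0.0, 0.1, -0.1, 0.05])
        res = stats.tukey_hsd(
            {"A": base, "B": base + 0.5, "C": base + 2.0}
        ).set_index(["group_1", "group_2"])
        assert res.loc[("A", "C"), "p_adj"] <= res.loc[("A", "B"), "p_adj"]


class TestConfidenceInterval:
    def test_hand_computed(self):
        mean, lo, hi = stats.t_confidence_interval(np.array([0.6, 0.7, 0.8]))
        assert mean == pytest.approx(0.7)
        assert lo == pytest.approx(0.4516, abs=1e-4)
        assert hi == pytest.approx(0.9484, abs=1e-4)

    def test_constant_zero_width(self):
        mean, lo, hi = stats.t_confidence_interval(np.full(5, 0.42))
        assert mean == pytest.approx(0.42)
        assert lo == pytest.approx(mean, abs=1e-12)
        assert hi == pytest.approx(mean, abs=1e-12)

    def test_level_monotonicity(self):
        vals = np.array([0.1, 0.5, 0.3, 0.7])
        _, lo95, hi95 = stats.t_confidence_interval(vals, 0.95)
        _, lo99, hi99 = stats.t_confidence_interval(vals, 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            stats.t_confidence_interval(np.array([1.0]))


class TestNormalizeConfusion:
    def test_simple(self):
        pct = stats.normalize_confusion(CM2)
        assert pct == pytest.approx(np.array([[90.0, 10.0], [20.0, 80.0]]))

    @given(
        st.lists(
            st.lists(st.integers(0, 50), min_size=3, max_size=3),
            min_size=3, max_size=3,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rows_sum_to_100(self, counts):
        arr = np.array(counts)
        cm = ConfusionMatrix(["a", "b", "c"], arr)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pct = stats.normalize_confusion(cm)
        for i, row in enumerate(arr):
            if row.sum() > 0:
                assert pct[i].sum() == pytest.approx(100.0, abs=1e-6)
            else:
                assert (pct[i] == 0).all()

    def test_identity_counts(self):
        cm = ConfusionMatrix(["a", "b"], np.eye(2, dtype=int) * 7)
        assert np.allclose(np.diag(stats.normalize_confusion(cm)), 100.0)


CM3 = ConfusionMatrix(
    ["a", "b", "c"], np.array([[15, 3, 0], [1, 16, 1], [0, 0, 18]])
)


class TestSimilarityNetwork:
    def test_edge_weight_formula(self):
        g = net.build_similarity_network(CM3)
        assert g["a"]["b"]["weight"] == pytest.approx(4 / 36)
        assert not g.has_edge("a", "c")
        assert g.has_edge("b", "c")

    def test_diagonal_matrix_is_edgeless(self):
        g = net.build_similarity_network(
            ConfusionMatrix(["a", "b"], np.diag([4, 6]))
        )
        assert g.number_of_edges() == 0

    def test_symmetric_under_transpose(self):
        # the error numerator (C_ij + C_ji) is transpose-symmetric, so
        # the edge *set* always is; weights also agree whenever row
        # and column totals coincide (as in CV output with no dropped
        # instances per class... here: doubly balanced counts)
        balanced = ConfusionMatrix(
            ["a", "b", "c"],
            np.array([[15, 2, 1], [2, 14, 2], [1, 2, 15]]),
        )
        for cm in (CM3, balanced):
            cmt = ConfusionMatrix(cm.labels, cm.counts.T)
            g1 = net.build_similarity_network(cm)
            g2 = net.build_similarity_network(cmt)
            assert {frozenset(e) for e in g1.edges} == {
                frozenset(e) for e in g2.edges
            }
        g1 = net.build_similarity_network(balanced)
        g2 = net.build_similarity_network(
            ConfusionMatrix(balanced.labels, balanced.counts.T)
        )
        for u, v in g1.edges:
            assert g1[u][v]["weight"] == pytest.approx(g2[u][v]["weight"])

    def test_weights_reconstruct_offdiagonal_mass(self):
        g = net.build_similarity_network(CM3)
        counts = CM3.counts
        row = counts.sum(axis=1)
        for i, a in enumerate(CM3.labels):
            total = sum(
                g[a][b]["weight"] * (row[i] + row[j])
                for j, b in enumerate(CM3.labels)
                if g.has_edge(a, b)
            )
            expect = counts[i].sum() - counts[i, i] + counts[:, i].sum() - counts[i, i]
            assert total == pytest.approx(expect)

    def test_node_attributes(self):
        g = net.build_similarity_network(CM3)
        assert g.nodes["c"]["accuracy_pct"] == pytest.approx(100.0)
        assert g.nodes["a"]["support"] == 18


class TestLayout:
    def test_single_node_at_origin(self):
        g = nx.Graph()
        g.add_node("only")
        pos = net.fr_layout(g, seed=0)
        assert np.allclose(pos["only"], 0)

    def test_deterministic(self):
        g = net.build_similarity_network(CM3)
        a = net.fr_layout(g, seed=3)
        b = net.fr_layout(g, seed=3)
        for n in g.nodes:
            assert np.allclose(a[n], b[n])

    def test_heavier_edge_pulls_nodes_closer(self):
        def pair_distance(w, seed):
            g = nx.Graph()
            g.add_nodes_from("abcd")
            g.add_edge("a", "b", weight=w)
            g.add_edge("c", "d", weight=0.05)
            pos = net.fr_layout(g, seed=seed)
            return np.linalg.norm(pos["a"] - pos["b"])

        strong = np.mean([pair_distance(1.0, s) for s in range(10)])
        weak = np.mean([pair_distance(0.5, s) for s in range(10)])
        assert strong < weak

    def test_weight_anticorrelates_with_distance(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        counts = np.diag([30] * 6)
        for (i, j) in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (2, 3)]:
            c = int(rng.integers(1, 12))
            counts[i, j] += c
            counts[j, i] += c // 2
        cm = ConfusionMatrix(list("abcdef"), counts)
        g = net.build_similarity_network(cm)
        assert g.number_of_edges() >= 5
        corrs = []
        for seed in range(10):
            pos = net.fr_layout(g, seed=seed)
            ws, ds = [], []
            for u, v, d in g.edges(data=True):
                ws.append(d["weight"])
                ds.append(-np.linalg.norm(pos[u] - pos[v]))
            corrs.append(spearmanr(ws, ds).statistic)
        assert np.mean(corrs) > 0


class TestRenderOutputs:
    def test_files_written_and_roundtrip(self, tmp_path):
        g = net.build_similarity_network(CM3)
        paths = net.render_outputs(CM3, g, tmp_path, layout_seed=1)
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        g2 = nx.read_graphml(paths["graphml"])
        assert set(g2.nodes) == set(g.nodes)
        assert {frozenset(e) for e in g2.edges} == {frozenset(e) for e in g.edges}
        for u, v in g.edges:
            assert g2[u][v]["weight"] == pytest.approx(g[u][v]["weight"])
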