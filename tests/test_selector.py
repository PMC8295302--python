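"""Core selector: splits, ANOVA filter, group networks, PRV scoring."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from prognet.datatypes import ClinicalTable, ExpressionMatrix
from prognet.selector import (
    ALL_CRITERIA,
    SelectorParams,
    SplitCriterion,
    WeightedNetwork,
    anova_filter,
    build_group_network,
    compute_prv,
    make_split,
    run_selector,
)


def _expr(data, samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else data
    if samples is not None:
        df.columns = samples
    return ExpressionMatrix(df)


def _clin(rows):
    return ClinicalTable(pd.DataFrame.from_dict(rows, orient="index"))


def _status_row(er="positive", pr="positive", her2="negative"):
    return {
        "er_status": er, "pr_status": pr, "her2_status": her2,
        "survival_time_months": 1.0, "event": "alive",
    }


class TestMakeSplit:
    def test_er_status_split(self):
        clin = _clin({
            "s1": _status_row(er="positive"),
            "s2": _status_row(er="negative"),
            "s3": _status_row(er="unknown"),
        })
        expr = _expr(pd.DataFrame(
            np.zeros((1, 3)), index=["GA"], columns=["s1", "s2", "s3"]
        ))
        g = make_split(SplitCriterion("ER"), expr, clin)
        assert g.group_a == ["s1"]
        assert g.group_b == ["s2"]
        assert g.excluded == ["s3"]

    def test_triple_negative_goes_to_group_a(self):
        clin = _clin({
            "s1": _status_row("negative", "negative", "negative"),
            "s2": _status_row("positive", "negative", "negative"),
        })
        expr = _expr(pd.DataFrame(
            np.zeros((1, 2)), index=["GA"], columns=["s1", "s2"]
        ))
        g = make_split(SplitCriterion("TN"), expr, clin)
        assert g.group_a == ["s1"]
        assert g.group_b == ["s2"]

    def test_hp_requires_both_receptors_positive(self):
        clin = _clin({
            "s1": _status_row("positive", "positive"),
            "s2": _status_row("positive", "negative"),
        })
        expr = _expr(pd.DataFrame(
            np.zeros((1, 2)), index=["GA"], columns=["s1", "s2"]
        ))
        g = make_split(SplitCriterion("HP"), expr, clin)
        assert g.group_a == ["s1"]
        assert g.group_b == ["s2"]

    def test_median_split_ties_to_group_b(self):
        samples = ["s1", "s2", "s3", "s4"]
        clin = _clin({s: _status_row() for s in samples})
        expr = _expr(pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0]], index=["MKI67"], columns=samples
        ))
        g = make_split(SplitCriterion("MKI67"), expr, clin)
        # median 2.5: top two above, bottom two at-or-below
        assert sorted(g.group_a) == ["s3", "s4"]
        assert sorted(g.group_b) == ["s1", "s2"]

    def test_missing_marker_gene(self):
        clin = _clin({"s1": _status_row()})
        expr = _expr(pd.DataFrame(
            np.zeros((1, 1)), index=["GA"], columns=["s1"]
        ))
        with pytest.raises(ValueError, match="PLAU"):
            make_split(SplitCriterion("PLAU"), expr, clin)

    def test_unknown_criterion_rejected(self):
        with pytest.raises(ValueError):
            SplitCriterion("KI67")


class TestAnovaFilter:
    def _groups(self, na, nb):
        from prognet.selector import GroupAssignment
        return GroupAssignment(
            [f"a{i}" for i in range(na)], [f"b{i}" for i in range(nb)], []
        )

    def test_invariant_gene_filtered(self):
        g = self._groups(3, 3)
        expr = _expr(pd.DataFrame(
            [[1.0] * 6], index=["GA"], columns=g.group_a + g.group_b
        ))
        retained, p = anova_filter(expr, g, alpha=0.05)
        assert retained == []
        assert p["GA"] == 1.0

    def test_strong_separation_retained(self):
        rng = np.random.default_rng(0)
        g = self._groups(20, 20)
        vals = np.concatenate([rng.normal(0, 1, 20), rng.normal(5, 1, 20)])
        expr = _expr(pd.DataFrame(
            vals[None, :], index=["GA"], columns=g.group_a + g.group_b
        ))
        retained, p = anova_filter(expr, g, alpha=0.05)
        assert retained == ["GA"]
        assert p["GA"] < 1e-10

    def test_matches_scipy_two_sample_t(self):
        rng = np.random.default_rng(1)
        g = self._groups(8, 11)
        x = rng.standard_normal((5, 19))
        expr = _expr(pd.DataFrame(
            x, index=[f"G{i}" for i in range(5)],
            columns=g.group_a + g.group_b,
        ))
        _, p = anova_filter(expr, g, alpha=0.05)
        from scipy import stats
        for i in range(5):
            ref = stats.ttest_ind(x[i, :8], x[i, 8:], equal_var=True).pvalue
            assert p.iloc[i] == pytest.approx(ref, abs=1e-12)

    def test_degenerate_alpha_one(self):
        rng = np.random.default_rng(2)
        g = self._groups(4, 4)
        expr = _expr(pd.DataFrame(
            rng.standard_normal((3, 8)),
            index=["G0", "G1", "G2"], columns=g.group_a + g.group_b,
        ))
        retained, _ = anova_filter(expr, g, alpha=1.0)
        assert retained == ["G0", "G1", "G2"]


class TestGroupNetwork:
    def test_hand_computed_pearson_weights(self):
        samples = ["s1", "s2", "s3", "s4"]
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0],
             [2.0, 1.0, 4.0, 3.0],
             [1.0, 1.0, 2.0, 0.0]],
            index=["GA", "GB", "GC"], columns=samples,
        )
        net = nx.Graph([("GA", "GB"), ("GB", "GC"), ("GA", "GC")])
        wn = build_group_network(
            ExpressionMatrix(df), ["GA", "GB", "GC"], net, samples
        )
        for a, b in net.edges():
            expected = np.corrcoef(df.loc[a], df.loc[b])[0, 1]
            assert wn.weights[frozenset((a, b))] == pytest.approx(
                expected, abs=1e-12
            )

    def test_identical_profiles_weight_one(self):
        samples = ["s1", "s2", "s3"]
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]],
            index=["GA", "GB"], columns=samples,
        )
        wn = build_group_network(
            ExpressionMatrix(df), ["GA", "GB"], nx.Graph([("GA", "GB")]),
            samples,
        )
        assert wn.weights[frozenset(("GA", "GB"))] == pytest.approx(1.0)

    def test_filtered_endpoint_removes_edge(self):
        samples = ["s1", "s2", "s3"]
        df = pd.DataFrame(
            np.arange(9, dtype=float).reshape(3, 3),
            index=["GA", "GB", "GC"], columns=samples,
        )
        wn = build_group_network(
            ExpressionMatrix(df), ["GA", "GC"],
            nx.Graph([("GA", "GB"), ("GA", "GC")]), samples,
        )
        assert frozenset(("GA", "GB")) not in wn.weights
        assert frozenset(("GA", "GC")) in wn.weights

    def test_constant_gene_weight_zero(self):
        samples = ["s1", "s2", "s3"]
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]],
            index=["GA", "GB"], columns=samples,
        )
        wn = build_group_network(
            ExpressionMatrix(df), ["GA", "GB"], nx.Graph([("GA", "GB")]),
            samples,
        )
        assert wn.weights[frozenset(("GA", "GB"))] == 0.0


class TestComputePRV:
    def _nets(self, nodes, wa, wb):
        a = WeightedNetwork(nodes, {frozenset(k): v for k, v in wa.items()})
        b = WeightedNetwork(nodes, {frozenset(k): v for k, v in wb.items()})
        return a, b

    def test_identical_networks_zero(self):
        w = {("g", "p"): 0.5, ("g", "q"): -0.3}
        a, b = self._nets(["g", "p", "q"], w, w)
        prv = compute_prv(a, b)
        assert (prv == 0).all()

    def test_hand_example(self):
        a, b = self._nets(
            ["g", "p", "q"],
            {("g", "p"): 0.8, ("g", "q"): -0.2},
            {("g", "p"): -0.2, ("g", "q"): 0.4},
        )
        prv = compute_prv(a, b)
        assert prv["g"] == pytest.approx(0.8)   # (1.0 + 0.6) / 2
        assert prv["p"] == pytest.approx(1.0)
        assert prv["q"] == pytest.approx(0.6)

    def test_unnormalized_variant(self):
        a, b = self._nets(
            ["g", "p", "q"],
            {("g", "p"): 0.8, ("g", "q"): -0.2},
            {("g", "p"): -0.2, ("g", "q"): 0.4},
        )
        prv = compute_prv(a, b, normalization="sum")
        assert prv["g"] == pytest.approx(1.6)

    def test_isolated_gene_scores_zero(self):
        a, b = self._nets(["g", "p", "iso"],
                          {("g", "p"): 1.0}, {("g", "p"): 0.0})
        prv = compute_prv(a, b)
        assert prv["iso"] == 0.0

    def test_mismatched_nodes_rejected(self):
        a = WeightedNetwork(["g"], {})
        b = WeightedNetwork(["h"], {})
        with pytest.raises(ValueError):
            compute_prv(a, b)

    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_oracle(self, seed):
        """PRV equals per-edge brute-force recomputation on small graphs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        nodes = [f"g{i}" for i in range(n)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(n) for j in range(i + 1, n)
            if rng.random() < 0.4
        ]
        wa = {frozenset(e): float(rng.uniform(-1, 1)) for e in edges}
        wb = {frozenset(e): float(rng.uniform(-1, 1)) for e in edges}
        prv = compute_prv(
            WeightedNetwork(nodes, wa), WeightedNetwork(nodes, wb)
        )
        for g in nodes:
            incident = [e for e in wa if g in e]
            expected = (
                sum(abs(wa[e] - wb[e]) for e in incident) / len(incident)
                if incident else 0.0
            )
            assert prv[g] == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        nodes = ["a", "b", "c", "d"]
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("a", "d")]
        wa = {frozenset(e): float(rng.uniform(-1, 1)) for e in edges}
        wb = {frozenset(e): float(rng.uniform(-1, 1)) for e in edges}
        na, nb = WeightedNetwork(nodes, wa), WeightedNetwork(nodes, wb)
        forward = compute_prv(na, nb)
        backward = compute_prv(nb, na)
        pd.testing.assert_series_equal(forward, backward)
        assert ((forward >= 0) & (forward <= 2)).all()


class TestRunSelector:
    def test_permutation_invariance(self, small_cohort):
        cfg, network, expression, clinical, truth = small_cohort
        scores, _ = run_selector(
            SplitCriterion("ER"), expression, clinical, network
        )
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(expression.samples))
        scores_perm, _ = run_selector(
            SplitCriterion("ER"), expression.subset_samples(perm),
            clinical, network,
        )
        pd.testing.assert_series_equal(scores, scores_perm)

    def test_label_blindness(self, small_cohort):
        """Changing survival outcomes must not change the selector output."""
        cfg, network, expression, clinical, truth = small_cohort
        scores, _ = run_selector(
            SplitCriterion("HP"), expression, clinical, network
        )
        relabeled = clinical.data.copy()
        relabeled["survival_time_months"] = 1.0
        relabeled["event"] = "disease_death"
        scores2, _ = run_selector(
            SplitCriterion("HP"), expression,
            ClinicalTable(relabeled), network,
        )
        pd.testing.assert_series_equal(scores, scores2)

    def test_min_group_size_guard(self, small_cohort):
        cfg, network, expression, clinical, truth = small_cohort
        with pytest.raises(ValueError, match="criterion"):
            run_selector(
                SplitCriterion("ER"), expression, clinical, network,
                params=SelectorParams(min_group_size=10**6),
            )

    def test_planted_genes_recovered(self, default_cohort):
        from prognet.simulate import truth_recall_at_k

        cfg, network, expression, clinical, truth = default_cohort
        _, ranking = run_selector(
            SplitCriterion("ER"), expression, clinical, network
        )
        assert truth_recall_at_k(ranking, truth, 50) >= 0.6
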