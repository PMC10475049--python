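"""DE scoring, subgraph queries, and biomarker-panel clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from binn import (PathwayGraph, QuantDataset, de_score,
                  differential_expression, evaluate_panel, extract_subgraph,
                  layerize, panel_from_de, panel_from_importance)
from sklearn.metrics import rand_score

from _oracles import (rand_index_oracle, reachability_oracle,
                      two_stage_bh_oracle)
from conftest import random_dag


def two_group_data(g0_values, g1_values, proteins=None):
    X = np.vstack([g0_values, g1_values])
    labels = ["A"] * len(g0_values) + ["B"] * len(g1_values)
    proteins = proteins or [f"p{j}" for j in range(X.shape[1])]
    idx = [f"s{i}" for i in range(len(X))]
    return QuantDataset(pd.DataFrame(X, index=idx, columns=proteins),
                        pd.Series(labels, index=idx))


class TestDifferentialExpression:
    def test_equal_groups_fc_zero(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(size=(12, 1))
        data = two_group_data(noise[:6] - noise[:6].mean(axis=0),
                              noise[:6] - noise[:6].mean(axis=0))
        table = differential_expression(data)
        assert table["log2_fc"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_six_vs_six_matches_t_closed_form(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.5, 6)
        g0 = base[:, None]
        g1 = (base + 1.0)[:, None]
        table = differential_expression(two_group_data(g0, g1))
        # hand-computed pooled two-sample t on the same values
        m0, m1 = g0.mean(), g1.mean()
        sp = np.sqrt(((g0.std(ddof=1) ** 2) * 5 + (g1.std(ddof=1) ** 2) * 5)
                     / 10)
        t = (m1 - m0) / (sp * np.sqrt(1 / 6 + 1 / 6))
        p = 2 * sps.t.sf(abs(t), df=10)
        assert table["log2_fc"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        assert table["p_value"].iloc[0] == pytest.approx(p, abs=1e-6)

    def test_bh_adjustment_matches_step_up_oracle(self):
        rng = np.random.default_rng(2)
        # craft 4 proteins whose p-values land near the classic vector,
        # then check adjusted values against the two-stage oracle exactly
        data = two_group_data(rng.normal(size=(8, 4)),
                              rng.normal(size=(8, 4)) + [2, 1.5, 1, 0.5])
        table = differential_expression(data)
        expected = two_stage_bh_oracle(table["p_value"].to_numpy())
        assert np.allclose(table["p_adjusted"].to_numpy(), expected)

    def test_sparse_group_flagged(self):
        nan = np.nan
        data = two_group_data([[1.0], [nan], [nan], [nan]],
                              [[1.0], [2.0], [3.0], [2.5]])
        table = differential_expression(data)
        assert bool(table["flagged"].iloc[0])
        assert np.isnan(table["p_value"].iloc[0])

    def test_requires_two_groups(self):
        data = QuantDataset(pd.DataFrame(np.eye(3), index=list("abc")),
                            pd.Series(["A", "A", "A"], index=list("abc")))
        with pytest.raises(ValueError, match="two groups"):
            differential_expression(data)


class TestDEScore:
    def make_table(self, fcs, ps):
        return pd.DataFrame({"protein": [f"p{i}" for i in range(len(fcs))],
                             "log2_fc": fcs, "p_value": ps,
                             "p_adjusted": ps, "flagged": False})

    def test_double_extreme_is_sqrt2(self):
        table = de_score(self.make_table([2.0, 1.0], [1e-6, 1e-3]))
        assert table["de_score"].iloc[0] == pytest.approx(np.sqrt(2))

    def test_three_four_five(self):
        # ratios (0.6, 0.8): |FC| 0.6 of max, log p 0.8 of min
        ps = [np.exp(-8.0), np.exp(-10.0)]
        table = de_score(self.make_table([0.6, 1.0], ps))
        assert table["de_score"].iloc[0] == pytest.approx(1.0)

    def test_axis_case(self):
        table = de_score(self.make_table([0.0, 1.0],
                                         [np.exp(-5.0), np.exp(-10.0)]))
        assert table["de_score"].iloc[0] == pytest.approx(0.5)

    def test_scale_invariance_in_fc(self):
        fcs, ps = [0.3, -0.9, 0.6], [1e-2, 1e-4, 1e-3]
        t1 = de_score(self.make_table(fcs, ps))
        t2 = de_score(self.make_table([f * 7.7 for f in fcs], ps))
        assert np.allclose(t1["de_score"], t2["de_score"])

    def test_degenerate_all_zero_fc(self):
        with pytest.raises(ValueError, match="degenerate"):
            de_score(self.make_table([0.0, 0.0], [0.01, 0.2]))


class TestSubgraphExtraction:
    def test_downstream_from_protein(self, g0_spec):
        sg = extract_subgraph(g0_spec, None, "P1", "downstream")
        assert sg.nodes == {"P1", "A__copy_l1", "A", "R", "output_0"}

    def test_upstream_from_root(self, g0_spec):
        sg = extract_subgraph(g0_spec, None, "R", "upstream")
        assert sg.nodes == {"R", "A", "B", "A__copy_l1", "B__copy_l1",
                            "P1", "P2", "P3"}

    def test_complete_is_union(self, g0_spec):
        down = extract_subgraph(g0_spec, None, "A", "downstream")
        up = extract_subgraph(g0_spec, None, "A", "upstream")
        comp = extract_subgraph(g0_spec, None, "A", "complete")
        assert comp.nodes == down.nodes | up.nodes
        assert comp.edges == down.edges | up.edges

    def test_unknown_anchor(self, g0_spec):
        with pytest.raises(KeyError):
            extract_subgraph(g0_spec, None, "zzz", "downstream")

    def test_collapse_copies(self, g0_spec):
        sg = extract_subgraph(g0_spec, None, "P1", "downstream",
                              collapse_copies=True)
        assert sg.nodes == {"P1", "A", "R", "output_0"}
        assert ("P1", "A") in sg.edges

    def test_importance_carried_over(self, g0_spec):
        table = pd.DataFrame({"node": ["P1", "A"], "adjusted": [0.4, 0.9]})
        sg = extract_subgraph(g0_spec, table, "P1", "downstream")
        assert sg.importance == {"P1": 0.4, "A": 0.9}

    def test_matches_bruteforce_on_random_specs(self):
        from binn import layerize as lz
        from binn.pathway_graph import GraphError
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 25:
            g = random_dag(rng, max_pathways=18, max_proteins=6)
            try:
                spec = lz(g, sorted(g.protein_map), int(rng.integers(1, 5)))
            except GraphError:
                continue
            nodes = [n for layer in spec.layers for n in layer]
            anchor = nodes[int(rng.integers(0, len(nodes)))]
            for direction in ("downstream", "upstream", "complete"):
                sg = extract_subgraph(spec, None, anchor, direction)
                assert sg.nodes == reachability_oracle(spec, anchor, direction)
            checked += 1


class TestPanelEvaluation:
    def test_perfectly_separating_panel(self):
        rng = np.random.default_rng(3)
        g0 = rng.normal(0, 0.1, (10, 3))
        g1 = rng.normal(5, 0.1, (10, 3))
        data = two_group_data(g0, g1)
        scores = pd.Series([3.0, 2.0, 1.0], index=["p0", "p1", "p2"])
        ev = evaluate_panel(data, scores, m=2)
        assert ev.rand_index == 1.0
        assert ev.panel == ["p0", "p1"]

    def test_orthogonal_clustering_rand_third(self):
        # clustering will find {s0,s1} vs {s2,s3}; truth alternates -> 1/3
        X = np.array([[0.0], [0.1], [5.0], [5.1]])
        data = QuantDataset(
            pd.DataFrame(np.hstack([X, X]), index=list("abcd"),
                         columns=["p0", "p1"]),
            pd.Series(["A", "B", "A", "B"], index=list("abcd")))
        ev = evaluate_panel(data, pd.Series([1.0, 0.5], index=["p0", "p1"]),
                            m=2)
        assert ev.rand_index == pytest.approx(1 / 3)

    def test_rand_matches_pair_counting_on_random_labelings(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            a = rng.integers(0, 3, 12)
            b = rng.integers(0, 3, 12)
            assert rand_score(a, b) == pytest.approx(rand_index_oracle(a, b))

    def test_m_too_small_rejected(self):
        data = two_group_data(np.eye(3), np.eye(3))
        with pytest.raises(ValueError, match="m"):
            evaluate_panel(data, pd.Series([1.0], index=["p0"]), m=1)

    def test_shap_panel_beats_random_panels(self, planted_run):
        """Importance-ranked panel clusters the classes better than chance."""
        from binn import adjust, aggregate, attribute
        model, spec, prep, data = (planted_run["model"], planted_run["spec"],
                                   planted_run["prep"], planted_run["data"])
        attrs = attribute(model, prep.to_input(spec))
        table = adjust(aggregate(attrs, spec), spec)
        shap_rand = evaluate_panel(data, panel_from_importance(table),
                                   m=20).rand_index
        rng = np.random.default_rng(0)
        rand_rands = []
        for _ in range(20):
            fake = pd.Series(rng.random(len(data.proteins)),
                             index=data.proteins)
            rand_rands.append(evaluate_panel(data, fake, m=20).rand_index)
        assert shap_rand >= np.mean(rand_rands)

    def test_de_ranking_source(self, planted_run):
        data, truth = planted_run["data"], planted_run["truth"]
        table = de_score(differential_expression(data))
        scores = panel_from_de(table)
        top10 = set(scores.index[:10])
        assert len(top10 & set(truth["affected_proteins"])) >= 8
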