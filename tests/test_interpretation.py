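"""Attribution exactness, connectivity correction, and Sankey flows."""

import numpy as np
import pandas as pd
import pytest

from binn import (PathwayGraph, adjust, aggregate, attribute, build_model,
                  head_attributions, layerize, subgraph_size)
from binn.interpretation import (Attributions, degree_threshold_adjust,
                                 log_subgraph_adjust, sankey_export)

from _oracles import subgraph_size_oracle
from conftest import random_dag


def zeroed_affine(model):
    """Make every block's affine part pass-through: bias 0, bn identity.

    With a zero background the reference activation is then exactly zero
    in every layer, which the closed-form attribution checks rely on.
    """
    for i in range(1, model.n_hidden + 1):
        model.params[f"b{i}"][:] = 0
        model.params[f"beta{i}"][:] = 0
        model.running[f"mean{i}"][:] = 0
        model.running[f"var{i}"][:] = 1.0 - 1e-5  # invstd exactly 1
    return model


class TestClosedForms:
    def test_linear_map_attribution_is_w_times_x(self, g0_spec):
        """Against a zero background, a linear map's attribution is w_i*x_i.

        The network is driven into its linear regime with a tiny batch-norm
        gain, so the only nonlinearity (tanh) acts as identity to first
        order and the chain masked-linear -> head is an exact linear map.
        """
        rng = np.random.default_rng(0)
        model = zeroed_affine(build_model(g0_spec, p_drop=0.0, seed=0))
        for i in range(1, 4):
            model.params[f"gamma{i}"][:] = 1e-4
        X = rng.normal(size=(5, 3))
        bg = np.zeros((1, 3))
        per_layer, expected = head_attributions(model, X, bg, head=1)
        W = model.params["W1"] * 1e-4          # effective linear map to y1
        U = model.params["U1"][:, 0]
        manual = (X[:, :, None] * W[None]) @ U  # w_i x_i per input node
        assert expected == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(per_layer[0], manual, rtol=1e-6, atol=1e-12)

    def test_all_zero_weights_give_zero_attributions(self, g0_spec):
        model = build_model(g0_spec, p_drop=0.0, seed=0)
        for i in range(1, 4):
            model.params[f"W{i}"][:] = 0
            model.params[f"U{i}"][:] = 0
        attrs = attribute(model, np.random.default_rng(1).normal(size=(4, 3)),
                          allow_unfitted=True)
        assert all(np.allclose(v, 0) for v in attrs.values)


class TestCompleteness:
    """Local accuracy: attributions sum to f(x) - E(f(x)) for every head."""

    @pytest.mark.parametrize("seed,n_classes", [(0, 1), (1, 1), (2, 3), (3, 2)])
    def test_sums_match_logit_difference(self, g0, seed, n_classes):
        rng = np.random.default_rng(seed)
        spec = layerize(g0, ["P1", "P2", "P3"], 3, n_classes)
        model = build_model(spec, p_drop=0.0, seed=seed)
        # arbitrary running stats, as after real training
        for i in range(1, 4):
            model.running[f"mean{i}"] = rng.normal(size=model.widths[i])
            model.running[f"var{i}"] = rng.uniform(0.5, 2.0, model.widths[i])
        X = rng.normal(size=(6, 3))
        bg = rng.normal(size=(9, 3))
        for head in (1, 2, 3):
            for cls in range(n_classes):
                per_layer, expected = head_attributions(model, X, bg,
                                                        head, cls)
                out = model.forward(X)
                fx = out.out_layer[head - 1][:, cls]
                for l in range(head + 1):
                    sums = per_layer[l].sum(axis=1)
                    assert np.allclose(sums, fx - expected, rtol=1e-9,
                                       atol=1e-9)

    def test_attribute_requires_fitted_model(self, g0_spec):
        model = build_model(g0_spec, seed=0)
        with pytest.raises(ValueError, match="not fitted"):
            attribute(model, np.zeros((2, 3)))


class TestAggregate:
    def test_absolute_value_before_mean(self, g0_spec):
        # two samples with attributions +1 and -1 on P1: S must be 1, not 0
        values = [np.zeros((2, len(layer), 1)) for layer in g0_spec.layers[:4]]
        values[0][:, 0, 0] = [1.0, -1.0]
        attrs = Attributions(values=values, layers=g0_spec.layers[:4],
                             class_names=["0"], expected_logits=[[0.0]] * 3)
        table = aggregate(attrs, g0_spec)
        assert table.loc[table.node == "P1", "S"].item() == 1.0

    def test_single_sample_and_homogeneity(self, planted_run):
        model, spec, prep = (planted_run["model"], planted_run["spec"],
                             planted_run["prep"])
        X = prep.to_input(spec)[:3]
        attrs = attribute(model, X, background=X)
        table = aggregate(attrs, spec)
        scaled = Attributions(values=[v * -2.5 for v in attrs.values],
                              layers=attrs.layers,
                              class_names=attrs.class_names,
                              expected_logits=attrs.expected_logits)
        table2 = aggregate(scaled, spec)
        assert np.allclose(table2["S"], 2.5 * table["S"])
        one = attribute(model, X[:1], background=X)
        t_one = aggregate(one, spec)
        assert np.allclose(t_one["S"],
                           np.abs(np.concatenate(
                               [v[0, :, :].mean(axis=1)
                                for v in one.values])))


class TestSubgraphSize:
    def test_toy_g0_root(self, g0_spec):
        # predecessors {A, B, copies, P1..P3} + successor {output} + self
        assert subgraph_size(g0_spec, "R") == 9

    def test_chain_node(self):
        g = PathwayGraph(edges=frozenset({("A", "R")}),
                         protein_map={"P": frozenset({"A", "R"})})
        spec = layerize(g, ["P"], n_hidden=4)
        # every chain node sees the whole chain: N+2 nodes
        assert subgraph_size(spec, "A__copy_l2") == 6

    def test_input_node_forward_reach(self, g0_spec):
        assert subgraph_size(g0_spec, "P3") == \
            subgraph_size_oracle(g0_spec, "P3") == 5

    def test_unknown_node_rejected(self, g0_spec):
        with pytest.raises(KeyError):
            subgraph_size(g0_spec, "nope")

    def test_matches_bruteforce_on_random_specs(self):
        rng = np.random.default_rng(9)
        from binn import layerize as lz
        from binn.pathway_graph import GraphError
        checked = 0
        while checked < 30:
            g = random_dag(rng, max_pathways=20, max_proteins=8)
            try:
                spec = lz(g, sorted(g.protein_map), int(rng.integers(1, 5)))
            except GraphError:
                continue
            for layer in spec.layers:
                for node in layer:
                    assert subgraph_size(spec, node) == \
                        subgraph_size_oracle(spec, node)
            checked += 1


class TestAdjust:
    def test_log_subgraph_closed_forms(self):
        assert log_subgraph_adjust([2.0], [np.e ** 2])[0] == pytest.approx(1.0)
        # N_SG <= e: denominator clamps to 1
        assert log_subgraph_adjust([0.7], [2])[0] == pytest.approx(0.7)
        assert log_subgraph_adjust([0.7], [1])[0] == pytest.approx(0.7)

    def test_degree_threshold_closed_forms(self):
        # below the mu + 5 sigma threshold: unchanged
        assert degree_threshold_adjust([3.0], [4], mu=2, sigma=1)[0] == 3.0
        # above: divided by the degree
        assert degree_threshold_adjust([3.0], [10], mu=2, sigma=1)[0] == 0.3

    def test_monotone_in_subgraph_size(self):
        sizes = np.arange(1, 200)
        vals = log_subgraph_adjust(np.full(sizes.shape, 5.0), sizes)
        assert (np.diff(vals) <= 1e-12).all()

    def test_adjust_table_integration(self, g0_spec):
        table = pd.DataFrame({
            "node": [n for layer in g0_spec.layers[:-1] for n in layer],
            "layer": [i for i, layer in enumerate(g0_spec.layers[:-1])
                      for _ in layer],
            "S__0": 1.0, "S": 1.0})
        out = adjust(table, g0_spec, "log_subgraph")
        r = out[out.node == "R"].iloc[0]
        assert r["N_SG"] == 9
        assert r["adjusted"] == pytest.approx(1.0 / np.log(9))
        ident = adjust(table, g0_spec, "none")
        assert np.allclose(ident["adjusted"], ident["S"])
        with pytest.raises(ValueError):
            adjust(table, g0_spec, "banana")


class TestSankey:
    @pytest.fixture
    def table(self, g0_spec):
        table = pd.DataFrame({
            "node": [n for layer in g0_spec.layers[:-1] for n in layer],
            "layer": [i for i, layer in enumerate(g0_spec.layers[:-1])
                      for _ in layer],
            "S__0": 1.0, "S": 1.0})
        return adjust(table, g0_spec, "none")

    def test_proportional_split(self, g0_spec, table):
        # P1 -> A_copy only in G0; craft a two-target case on layer 2->3
        table.loc[table.node == "A", "adjusted"] = 3.0
        table.loc[table.node == "B", "adjusted"] = 1.0
        table.loc[table.node == "A__copy_l1", "adjusted"] = 1.0
        data = sankey_export(table, g0_spec, top_k=10)
        flows = {(l["source"], l["target"]): l["flow"] for l in data["links"]}
        assert flows[("A__copy_l1", "A")] == pytest.approx(1.0)
        # P-level: each protein splits over its single target fully
        out_p1 = sum(v for (s, t), v in flows.items() if s == "P1")
        assert out_p1 == pytest.approx(
            table.loc[table.node == "P1", "adjusted"].item())

    def test_two_target_split(self):
        # graph where one child feeds two parents: C -> {R1, R2}
        g = PathwayGraph(edges=frozenset({("C", "R1"), ("C", "R2")}),
                         protein_map={"P": frozenset({"C", "R1", "R2"})})
        spec = layerize(g, ["P"], n_hidden=2)
        table = pd.DataFrame({
            "node": [n for layer in spec.layers[:-1] for n in layer],
            "layer": [i for i, layer in enumerate(spec.layers[:-1])
                      for _ in layer],
            "S__0": 1.0, "S": 1.0})
        table = adjust(table, spec, "none")
        table.loc[table.node == "C", "adjusted"] = 1.0
        table.loc[table.node == "R1", "adjusted"] = 3.0
        table.loc[table.node == "R2", "adjusted"] = 1.0
        data = sankey_export(table, spec, top_k=10)
        flows = {(l["source"], l["target"]): l["flow"] for l in data["links"]}
        assert flows[("C", "R1")] == pytest.approx(0.75)
        assert flows[("C", "R2")] == pytest.approx(0.25)

    def test_flow_conservation_and_no_other_pool(self, g0_spec, table):
        data = sankey_export(table, g0_spec, top_k=10)  # top_k >= layer sizes
        assert not any(n["id"].startswith("other_l") for n in data["nodes"])
        outgoing = {}
        for lk in data["links"]:
            outgoing[lk["source"]] = outgoing.get(lk["source"], 0) + lk["flow"]
        for node, val in outgoing.items():
            assert val == pytest.approx(
                table.loc[table.node == node, "adjusted"].item())

    def test_top_k_pooling(self, planted_run):
        model, spec, prep = (planted_run["model"], planted_run["spec"],
                             planted_run["prep"])
        attrs = attribute(model, prep.to_input(spec))
        table = adjust(aggregate(attrs, spec), spec)
        data = sankey_export(table, spec, top_k=3)
        others = [n for n in data["nodes"] if not n["labeled"]]
        assert others  # 100 proteins with top_k=3 must pool
        labeled_l0 = [n for n in data["nodes"]
                      if n["layer"] == 0 and n["labeled"]]
        assert len(labeled_l0) == 3
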