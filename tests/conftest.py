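import numpy as np
import pytest

from binn import (PathwayGraph, SimSpec, TrainConfig, build_model, layerize,
                  make_toy_graph, prepare, simulate_cohort, train)


@pytest.fixture(scope="session")
def g0():
    """The three-protein fan-in toy graph: A->R, B->R, proteins on A/A/B."""
    return PathwayGraph(
        edges=frozenset({("A", "R"), ("B", "R")}),
        protein_map={"P1": frozenset({"A", "R"}),
                     "P2": frozenset({"A", "R"}),
                     "P3": frozenset({"B", "R"})})


@pytest.fixture(scope="session")
def g0_spec(g0):
    return layerize(g0, ["P1", "P2", "P3"], n_hidden=3, n_classes=1)


def random_dag(rng, max_pathways=50, max_proteins=20):
    """A random pathway DAG with an all-levels protein mapping.

    Pathway indices are topologically ordered (edges point to higher
    indices = rootward), guaranteeing acyclicity; ancestor closure for the
    all-levels map is computed here by direct iteration, independently of
    the package.
    """
    n_pw = int(rng.integers(4, max_pathways + 1))
    n_prot = int(rng.integers(1, max_proteins + 1))
    names = [f"pw{i:02d}" for i in range(n_pw)]
    edges = set()
    for i in range(n_pw - 1):
        n_par = int(rng.integers(1, 3))
        parents = rng.choice(np.arange(i + 1, n_pw), size=min(n_par, n_pw - 1 - i),
                             replace=False)
        for j in parents:
            edges.add((names[i], names[int(j)]))
    parent_of = {}
    for c, p in edges:
        parent_of.setdefault(c, set()).add(p)

    def ancestors(pw):
        out, frontier = {pw}, [pw]
        while frontier:
            v = frontier.pop()
            for p in parent_of.get(v, ()):
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return out

    protein_map = {}
    for k in range(n_prot):
        base = names[int(rng.integers(0, n_pw - 1))]
        protein_map[f"prot{k:02d}"] = frozenset(ancestors(base))
    return PathwayGraph(edges=frozenset(edges), protein_map=protein_map)


@pytest.fixture(scope="session")
def planted_run():
    """One trained interpretation-mode model on the planted-effect cohort.

    Expensive (a full training run), so computed once per session and
    shared by the interpretation and panel tests.
    """
    sim = SimSpec(planted=[("PW_L2_000", 2.0, 10 / 12)], seed=1)
    graph = make_toy_graph(sim)
    data, truth = simulate_cohort(sim, graph)
    spec = layerize(graph, data.proteins, n_hidden=3, n_classes=1)
    prep = prepare(data)
    model = build_model(spec, seed=1)
    result = train(model, prep, TrainConfig(seed=1))
    return {"sim": sim, "graph": graph, "data": data, "truth": truth,
            "spec": spec, "prep": prep, "model": model, "result": result}
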