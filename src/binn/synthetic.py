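"""Toy pathway hierarchies and synthetic proteomic cohorts.

The generator emulates a normalized log-scale proteomics matrix: each
protein has a log-normal baseline (per-sample SD 1 after log), a planted
pathway carries a class-conditional additive shift of ``delta`` SD units
on a fraction of its proteins, and entries are removed missing-at-random
at a fixed rate.  The pathway hierarchy is a balanced tree rooted at a
single out-degree-0 process node, with proteins assigned to leaves and
the membership file emitted at all ancestor levels (the all-levels
dialect the layered compilation expects).  Everything is deterministic
per seed, so planted structure can be scored exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .pathway_graph import PathwayGraph
from .training_eval import QuantDataset

__all__ = ["SimSpec", "make_toy_graph", "simulate_cohort", "recovery_score",
           "write_fixture_files"]

ROOT_ID = "ROOT"


@dataclass
class SimSpec:
    """Parameters of the synthetic hierarchy and cohort.

    ``planted`` entries are ``(pathway_id, delta, fraction)``: the given
    fraction of the pathway's proteins is shifted by ``delta`` (in units
    of the per-protein SD, on the log scale, before standardization) in
    every class except the first, scaled by the class index for
    multi-class cohorts.
    """

    n_pathway_levels: int = 2
    branching: int = 3
    n_proteins: int = 100
    n_per_class: int = 100
    n_classes: int = 2
    planted: list = field(default_factory=list)
    missing_rate: float = 0.0
    baseline_mean: float = 12.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pathway_levels < 1 or self.branching < 1:
            raise ValueError("levels and branching must be >= 1")
        if self.n_proteins < 1:
            raise ValueError("at least one protein is required")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for _, delta, frac in self.planted:
            if delta < 0:
                raise ValueError("planted effect delta must be >= 0 "
                                 "(swap the classes for a negative shift)")
            if not 0.0 < frac <= 1.0:
                raise ValueError("planted fraction must be in (0, 1]")


def _pathway_id(level: int, index: int) -> str:
    return f"PW_L{level}_{index:03d}"


def make_toy_graph(sim: SimSpec) -> PathwayGraph:
    """Balanced pathway tree with proteins assigned to the leaves.

    Level ``l`` has ``branching**l`` pathways; leaves sit at
    ``n_pathway_levels``.  Proteins ``PROT_0000...`` are dealt to leaves
    round-robin and the membership map carries every ancestor level.
    """
    edges = set()
    prev = [ROOT_ID]
    levels = [prev]
    for level in range(1, sim.n_pathway_levels + 1):
        cur = []
        for i, parent in enumerate(prev):
            for b in range(sim.branching):
                child = _pathway_id(level, i * sim.branching + b)
                edges.add((child, parent))
                cur.append(child)
        levels.append(cur)
        prev = cur
    leaves = levels[-1]

    parents = {c: p for c, p in edges}

    def ancestors(pw):
        out = [pw]
        while pw in parents:
            pw = parents[pw]
            out.append(pw)
        return out

    protein_map = {}
    for j in range(sim.n_proteins):
        leaf = leaves[j % len(leaves)]
        protein_map[f"PROT_{j:04d}"] = frozenset(ancestors(leaf))
    return PathwayGraph(edges=frozenset(edges), protein_map=protein_map)


def leaf_proteins(graph: PathwayGraph, pathway: str) -> list:
    """Proteins whose membership includes ``pathway``, sorted."""
    return sorted(p for p, pws in graph.protein_map.items() if pathway in pws)


def simulate_cohort(sim: SimSpec, graph: PathwayGraph):
    """Draw a cohort from the generative model; returns (dataset, truth).

    The truth record lists the affected proteins, the planted pathways,
    and the generator parameters, for downstream recovery scoring.
    """
    rng = np.random.default_rng(sim.seed)
    proteins = sorted(graph.protein_map)
    n = sim.n_per_class * sim.n_classes
    baselines = rng.normal(sim.baseline_mean, sim.baseline_sd, len(proteins))
    X = rng.normal(0.0, 1.0, (n, len(proteins))) + baselines

    labels = np.repeat(np.arange(sim.n_classes), sim.n_per_class)
    affected: dict = {}
    for pathway, delta, frac in sim.planted:
        members = leaf_proteins(graph, pathway)
        if not members:
            raise ValueError(f"planted pathway {pathway!r} has no proteins")
        n_aff = max(1, int(round(frac * len(members))))
        chosen = members[:n_aff]  # deterministic: first members in sorted order
        affected[pathway] = chosen
        cols = [proteins.index(p) for p in chosen]
        for cls in range(1, sim.n_classes):
            rows = labels == cls
            X[np.ix_(rows, cols)] += delta * cls

    if sim.missing_rate > 0:
        drop = rng.random(X.shape) < sim.missing_rate
        X = np.where(drop, np.nan, X)

    sample_ids = [f"S{i:04d}" for i in range(n)]
    matrix = pd.DataFrame(X, index=sample_ids, columns=proteins)
    lab = pd.Series([f"class_{c}" for c in labels], index=sample_ids,
                    name="group")
    truth = {
        "planted_pathways": [pw for pw, _, _ in sim.planted],
        "affected_proteins": sorted(set().union(*affected.values()))
        if affected else [],
        "affected_by_pathway": affected,
        "sim": asdict(sim),
    }
    return QuantDataset(matrix, lab), truth


def recovery_score(truth: dict, importance: pd.DataFrame, level: str,
                   top_k: int) -> dict:
    """Fraction of planted entities in the top-k by adjusted importance.

    ``level="protein"`` ranks the input layer against the affected
    proteins; ``level="pathway"`` ranks each planted pathway within its
    own layer (copies resolved to their source).  Returns the hit
    fraction and each planted entity's rank (1-based; ties broken by
    node id for determinism).
    """
    col = "adjusted" if "adjusted" in importance.columns else "S"
    if level == "protein":
        targets = truth["affected_proteins"]
        sub = importance[importance["layer"] == 0]
        ranked = sub.sort_values([col, "node"], ascending=[False, True])
        order = list(ranked["node"])
        missing = [t for t in targets if t not in order]
        if missing:
            raise KeyError(f"planted proteins absent from the table: {missing[:5]}")
        ranks = {t: order.index(t) + 1 for t in targets}
    elif level == "pathway":
        targets = truth["planted_pathways"]
        ranks = {}
        for pw in targets:
            rows = importance[(importance["source"] == pw)
                              & (~importance["is_copy"])]
            if rows.empty:
                raise KeyError(f"planted pathway {pw!r} absent from the table")
            layer = int(rows.iloc[0]["layer"])
            sub = importance[importance["layer"] == layer]
            ranked = sub.sort_values([col, "node"], ascending=[False, True])
            ranks[pw] = list(ranked["node"]).index(rows.iloc[0]["node"]) + 1
    else:
        raise ValueError("level must be 'protein' or 'pathway'")
    hits = sum(1 for r in ranks.values() if r <= top_k)
    return {"hit_fraction": hits / len(ranks) if ranks else float("nan"),
            "ranks": ranks, "top_k": top_k}


def write_fixture_files(sim: SimSpec, out_dir: str) -> dict:
    """Emit hierarchy.tsv, mapping.tsv, matrix.tsv, design.tsv, truth.json.

    The hierarchy file uses the distribution dialect (parent, child); the
    mapping file is (protein, pathway) at all levels.  Returns the file
    paths.  Byte-identical across runs for a fixed SimSpec.
    """
    os.makedirs(out_dir, exist_ok=True)
    graph = make_toy_graph(sim)
    data, truth = simulate_cohort(sim, graph)
    paths = {k: os.path.join(out_dir, f"{k}.tsv")
             for k in ("hierarchy", "mapping", "matrix", "design")}
    with open(paths["hierarchy"], "w") as fh:
        for child, parent in sorted(graph.edges):
            fh.write(f"{parent}\t{child}\n")
    with open(paths["mapping"], "w") as fh:
        for prot in sorted(graph.protein_map):
            for pw in sorted(graph.protein_map[prot]):
                fh.write(f"{prot}\t{pw}\n")
    data.matrix.round(6).to_csv(paths["matrix"], sep="\t",
                                index_label="sample")
    pd.DataFrame({"sample": data.matrix.index,
                  "group": data.labels.values}).to_csv(
        paths["design"], sep="\t", index=False)
    paths["truth"] = os.path.join(out_dir, "truth.json")
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return paths
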