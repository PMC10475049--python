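"""Differential expression scoring, biomarker-panel evaluation, subgraphs.

The DE score places every protein in a standardized volcano plot and
takes its Euclidean distance from the origin:

    DE_p = sqrt( (|log2 FC_p| / max |log2 FC|)^2
               + (log p_p / min log p)^2 ),

so both coordinates lie in [0, 1] and the score in (0, sqrt(2)].  Group
differences are fitted per protein by ordinary least squares on a group
indicator (the pooled two-sample t-test on the slope) over detected
values only, with two-stage Benjamini-Hochberg correction.

Panels of top-ranked proteins are evaluated by Ward hierarchical
clustering of the scaled abundances, cutting the tree at the number of
classes and scoring agreement with the true labels by the Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score, rand_score
from statsmodels.stats.multitest import multipletests

from .interpretation import layered_adjacency, _closure
from .pathway_graph import LayeredSpec
from .training_eval import QuantDataset, prepare

__all__ = ["differential_expression", "de_score", "extract_subgraph",
           "Subgraph", "PanelEvaluation", "evaluate_panel",
           "panel_from_importance", "panel_from_de"]


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------


def differential_expression(data: QuantDataset) -> pd.DataFrame:
    """Per-protein two-group comparison on detected (non-missing) values.

    The matrix is assumed log2-scale, so the fold change is the difference
    of group means.  Proteins with fewer than two detected values in
    either group get an undefined p-value and are flagged.  Returns a
    table with ``protein``, ``log2_fc`` (second group minus first, groups
    in sorted label order), ``p_value``, ``p_adjusted`` (two-stage BH) and
    ``flagged``.
    """
    classes = data.classes
    if len(classes) != 2:
        raise ValueError("differential expression requires exactly two groups")
    g0 = data.labels == classes[0]
    g1 = data.labels == classes[1]
    rows = []
    for prot in data.proteins:
        col = data.matrix[prot]
        v0 = col[g0].dropna().to_numpy()
        v1 = col[g1].dropna().to_numpy()
        if len(v0) < 2 or len(v1) < 2:
            rows.append((prot, np.nan, np.nan, True))
            continue
        fc = float(v1.mean() - v0.mean())
        # pooled two-sample t == OLS t-statistic on a binary group indicator
        t, p = stats.ttest_ind(v1, v0, equal_var=True)
        rows.append((prot, fc, float(p), False))
    table = pd.DataFrame(rows, columns=["protein", "log2_fc", "p_value",
                                        "flagged"])
    ok = ~table["p_value"].isna()
    adjusted = np.full(len(table), np.nan)
    if ok.any():
        adjusted[ok.to_numpy()] = multipletests(
            table.loc[ok, "p_value"], method="fdr_tsbh")[1]
    table["p_adjusted"] = adjusted
    return table[["protein", "log2_fc", "p_value", "p_adjusted", "flagged"]]


def de_score(table: pd.DataFrame) -> pd.DataFrame:
    """Append the volcano-distance ``de_score`` column.

    Uses |log2 FC| (the volcano x-axis is symmetric) and the natural log
    of the p-value; any log base cancels in the ratio.  Flagged rows get
    an undefined score.
    """
    out = table.copy()
    ok = ~out["p_value"].isna()
    fc = np.abs(out.loc[ok, "log2_fc"].to_numpy(dtype=float))
    p = np.clip(out.loc[ok, "p_value"].to_numpy(dtype=float), 1e-300, 1.0)
    if not len(fc) or fc.max() == 0:
        raise ValueError("degenerate table: every fold change is zero")
    logp = np.log(p)
    if logp.min() >= 0:
        raise ValueError("degenerate table: every p-value is 1")
    score = np.sqrt((fc / fc.max()) ** 2 + (logp / logp.min()) ** 2)
    out["de_score"] = np.nan
    out.loc[ok, "de_score"] = score
    return out


# ---------------------------------------------------------------------------
# Subgraph extraction
# ---------------------------------------------------------------------------


@dataclass
class Subgraph:
    """A directional closure of the layered network around an anchor node."""

    anchor: str
    direction: str
    nodes: set
    edges: set
    importance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        import json
        doc = {"anchor": self.anchor, "direction": self.direction,
               "nodes": sorted(self.nodes),
               "edges": sorted(list(e) for e in self.edges),
               "importance": {k: self.importance[k]
                              for k in sorted(self.importance)}}
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def extract_subgraph(spec: LayeredSpec, table: pd.DataFrame | None,
                     anchor: str, direction: str = "downstream",
                     *, collapse_copies: bool = False) -> Subgraph:
    """Downstream / upstream / complete closure of the layered graph.

    ``downstream`` follows successors of the anchor, ``upstream`` follows
    predecessors, ``complete`` is their union; the anchor is always
    included.  Adjusted importances from ``table`` (if given) are carried
    over.  ``collapse_copies`` merges pass-through copy chains into their
    source pathway for display.
    """
    if direction not in ("downstream", "upstream", "complete"):
        raise ValueError(f"unknown direction {direction!r}")
    succ, pred = layered_adjacency(spec)
    if anchor not in succ:
        raise KeyError(f"unknown anchor node {anchor!r}")
    nodes = {anchor}
    edges = set()
    if direction in ("downstream", "complete"):
        down = _closure(succ, anchor) | {anchor}
        nodes |= down
        edges |= {(u, v) for u in down for v in succ[u] if v in down}
    if direction in ("upstream", "complete"):
        up = _closure(pred, anchor) | {anchor}
        nodes |= up
        edges |= {(u, v) for v in up for u in pred[v] if u in up}

    if collapse_copies:
        rename = {n: spec.annotations[n].copy_of
                  if spec.annotations[n].is_copy else n for n in nodes}
        nodes = set(rename.values())
        edges = {(rename[u], rename[v]) for u, v in edges
                 if rename[u] != rename[v]}

    importance = {}
    if table is not None and "adjusted" in table.columns:
        lut = dict(zip(table["node"], table["adjusted"]))
        importance = {n: float(lut[n]) for n in nodes if n in lut}
    return Subgraph(anchor=anchor, direction=direction, nodes=nodes,
                    edges=edges, importance=importance)


# ---------------------------------------------------------------------------
# Biomarker panel evaluation
# ---------------------------------------------------------------------------


def panel_from_importance(table: pd.DataFrame) -> pd.Series:
    """Protein ranking scores from an importance table's input layer."""
    col = "adjusted" if "adjusted" in table.columns else "S"
    sub = table[table["layer"] == 0]
    return pd.Series(sub[col].to_numpy(), index=sub["node"]).sort_values(
        ascending=False)


def panel_from_de(table: pd.DataFrame) -> pd.Series:
    """Protein ranking scores from a DE table with ``de_score``."""
    if "de_score" not in table.columns:
        raise ValueError("run de_score() first")
    sub = table.dropna(subset=["de_score"])
    return pd.Series(sub["de_score"].to_numpy(),
                     index=sub["protein"]).sort_values(ascending=False)


@dataclass
class PanelEvaluation:
    panel: list
    rand_index: float
    adjusted_rand_index: float
    cluster_labels: np.ndarray
    n_clusters: int


def evaluate_panel(data: QuantDataset, scores: pd.Series, m: int = 20,
                   *, n_clusters: int | None = None) -> PanelEvaluation:
    """Ward-cluster samples on a top-m protein panel; score by Rand index.

    The top ``m`` proteins by ``scores`` are selected, abundances are
    imputed and standardized per protein, samples are clustered with Ward
    linkage on Euclidean distances and the tree is cut at the number of
    classes.  Reports the (unadjusted) Rand index against the true labels,
    with the adjusted Rand index alongside.
    """
    if m < 2:
        raise ValueError("panel size m must be >= 2")
    available = [p for p in scores.index if p in data.matrix.columns]
    if len(available) < m:
        raise ValueError(f"only {len(available)} ranked proteins are in the "
                         f"dataset; cannot take a panel of {m}")
    panel = list(pd.Series(scores[available]).sort_values(
        ascending=False).index[:m])
    sub = QuantDataset(data.matrix[panel].copy(), data.labels.copy())
    X = prepare(sub).matrix.to_numpy()
    k = n_clusters or len(data.classes)
    Z = linkage(X, method="ward", metric="euclidean")
    clusters = fcluster(Z, t=k, criterion="maxclust")
    y = data.y_indices()
    return PanelEvaluation(panel=panel,
                           rand_index=float(rand_score(y, clusters)),
                           adjusted_rand_index=float(
                               adjusted_rand_score(y, clusters)),
                           cluster_labels=clusters, n_clusters=k)
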