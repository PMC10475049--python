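"""Layer-wise attribution, connectivity-corrected importance, Sankey export.

Node importance is computed with the DeepLIFT rescale rule against a set
of background samples, the same multiplier calculus Deep SHAP applies to
feed-forward networks: linear components (masked linear transforms,
eval-mode batch normalization, the head maps) propagate multipliers
exactly, and each tanh distributes its output difference proportionally
to its input difference.  Attributions therefore satisfy local accuracy
exactly: for any head, the attributions of a layer's nodes sum to the
head logit minus its background expectation, f(x) - E(f(x)).

Attributions are computed on the *logit* scale of each auxiliary head
(standard practice for classifier explanation; for a single masked linear
layer this reduces to the exact Shapley value w_i * x_i against a zero
background).  A node's attribution is averaged over the heads downstream
of its layer, matching the averaged multi-head prediction.

Raw importances S_n (mean |attribution| over samples, per class) are then
corrected for graph connectivity: the default divides by the natural log
of the size of the node's complete subgraph (all predecessors and
successors, the node included), and the degree-threshold alternative
divides by the total degree only for nodes above mu + 5 sigma.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import BinnModel, _BN_EPS
from .pathway_graph import LayeredSpec, degree_stats

__all__ = ["Attributions", "attribute", "head_attributions", "aggregate",
           "subgraph_size", "layered_adjacency", "adjust", "sankey_export",
           "log_subgraph_adjust", "degree_threshold_adjust"]


# ---------------------------------------------------------------------------
# Attribution
# ---------------------------------------------------------------------------


@dataclass
class Attributions:
    """Per-sample, per-node, per-class attribution values.

    ``values[l]`` has shape ``(n_samples, len(layers[l]), n_classes)`` for
    input and hidden layers ``l = 0..n_hidden``;
    ``expected_logits[h - 1]`` is the background mean logit of head ``h``.
    """

    values: list
    layers: list
    class_names: list
    expected_logits: list


def _eval_activations(model: BinnModel, X: np.ndarray):
    """Eval-mode layer activations [a_0..a_N] and bn pre-tanh inputs [y_1..y_N]."""
    a = np.asarray(X, dtype=float)
    acts, pre = [a], []
    for i in range(1, model.n_hidden + 1):
        z = a @ model.params[f"W{i}"] + model.params[f"b{i}"]
        invstd = 1.0 / np.sqrt(model.running[f"var{i}"] + _BN_EPS)
        y = model.params[f"gamma{i}"] * (z - model.running[f"mean{i}"]) * invstd \
            + model.params[f"beta{i}"]
        a = np.tanh(y)
        pre.append(y)
        acts.append(a)
    return acts, pre


def head_attributions(model: BinnModel, X, background, head: int, cls: int = 0):
    """Rescale-rule attributions of every layer w.r.t. one head logit.

    Returns ``(per_layer, expected)`` where ``per_layer[l]`` has shape
    ``(n_samples, width_l)`` for ``l = 0..head`` (layers above the head do
    not feed it) and ``expected`` is the background-mean logit.  For every
    sample and every layer ``l <= head`` the attributions sum exactly to
    ``logit(x) - expected``.
    """
    X = model._check_input(X)
    B = model._check_input(background)
    if not 1 <= head <= model.n_hidden:
        raise ValueError(f"head must be in 1..{model.n_hidden}")
    acts_x, pre_x = _eval_activations(model, X)
    acts_b, pre_b = _eval_activations(model, B)
    logits_b = acts_b[head] @ model.params[f"U{head}"][:, cls] \
        + model.params[f"c{head}"][cls]
    expected = float(logits_b.mean())

    n, R = X.shape[0], B.shape[0]
    out = [np.zeros((n, len(layer))) for layer in model.spec.layers[:head + 1]]
    gamma_invstd = [model.params[f"gamma{i}"]
                    / np.sqrt(model.running[f"var{i}"] + _BN_EPS)
                    for i in range(1, model.n_hidden + 1)]
    u = model.params[f"U{head}"][:, cls]

    for s in range(n):
        # multipliers per background reference, shape (R, width)
        M = np.broadcast_to(u, (R, u.size)).copy()
        delta_a = acts_x[head][s] - acts_b[head]          # (R, width_head)
        out[head][s] = (M * delta_a).mean(axis=0)
        for i in range(head, 0, -1):
            dy = pre_x[i - 1][s] - pre_b[i - 1]           # (R, width_i)
            dh = acts_x[i][s] - acts_b[i]
            small = np.abs(dy) < 1e-9
            rho = np.where(small, 1.0 - np.tanh(pre_x[i - 1][s]) ** 2,
                           dh / np.where(small, 1.0, dy))
            M = (M * rho) * gamma_invstd[i - 1]
            M = M @ model.params[f"W{i}"].T                # (R, width_{i-1})
            delta = acts_x[i - 1][s] - acts_b[i - 1]
            out[i - 1][s] = (M * delta).mean(axis=0)
    return out, expected


def attribute(model: BinnModel, X, background=None, *,
              class_names=None, allow_unfitted: bool = False) -> Attributions:
    """Attribute every input and hidden node, per sample and per class.

    ``background`` defaults to the full matrix ``X`` (whole-dataset
    expectation).  A node in layer ``l`` is attributed through every head
    downstream of it (heads ``max(l, 1)..N``) and the per-head values are
    averaged, mirroring the averaged multi-head prediction.
    """
    if not model.fitted and not allow_unfitted:
        raise ValueError("model is not fitted; train it before attribution "
                         "(or pass allow_unfitted=True)")
    if background is None:
        background = X
    N, c = model.n_hidden, model.c_out
    n = np.asarray(X).shape[0]
    values = [np.zeros((n, len(layer), c)) for layer in model.spec.layers[:N + 1]]
    counts = np.zeros(N + 1)
    expected = [[0.0] * c for _ in range(N)]
    for h in range(1, N + 1):
        for k in range(c):
            per_layer, exp_hk = head_attributions(model, X, background, h, k)
            expected[h - 1][k] = exp_hk
            for l in range(0, h + 1):
                values[l][:, :, k] += per_layer[l]
        counts[:h + 1] += 1
    for l in range(N + 1):
        values[l] /= counts[l]
    if class_names is None:
        class_names = [str(k) for k in range(c)]
    return Attributions(values=values, layers=model.spec.layers[:N + 1],
                        class_names=list(class_names),
                        expected_logits=expected)


# ---------------------------------------------------------------------------
# Aggregation into an importance table
# ---------------------------------------------------------------------------


def aggregate(attrs: Attributions, spec: LayeredSpec) -> pd.DataFrame:
    """Raw node importance S_n = mean over samples of |attribution|.

    Returns a table with one row per node: ``node``, ``layer``, ``source``,
    ``label``, ``is_copy``, one ``S__<class>`` column per class and the
    class-mean ``S``.
    """
    rows = []
    for l, layer_nodes in enumerate(attrs.layers):
        S = np.abs(attrs.values[l]).mean(axis=0)      # (width, c)
        for j, node in enumerate(layer_nodes):
            ann = spec.annotations[node]
            row = {"node": node, "layer": l, "source": ann.source,
                   "label": ann.label, "is_copy": ann.is_copy}
            for k, cname in enumerate(attrs.class_names):
                row[f"S__{cname}"] = float(S[j, k])
            row["S"] = float(S[j].mean())
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Connectivity correction
# ---------------------------------------------------------------------------


def layered_adjacency(spec: LayeredSpec):
    """Successor/predecessor maps over all nodes of the layered network."""
    succ: dict = {n: set() for layer in spec.layers for n in layer}
    pred: dict = {n: set() for layer in spec.layers for n in layer}
    for i, m in enumerate(spec.masks):
        src, dst = spec.layers[i], spec.layers[i + 1]
        for a, b in zip(*np.nonzero(m)):
            succ[src[a]].add(dst[b])
            pred[dst[b]].add(src[a])
    return succ, pred


def _closure(adj: dict, start: str) -> set:
    seen, frontier = set(), [start]
    while frontier:
        node = frontier.pop()
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


def subgraph_size(spec: LayeredSpec, node: str, *, _adj=None) -> int:
    """Size of the complete subgraph of ``node``: all of its predecessors
    and successors in the layered network, plus the node itself."""
    succ, pred = _adj if _adj is not None else layered_adjacency(spec)
    if node not in succ:
        raise KeyError(f"unknown node {node!r}")
    return len(_closure(succ, node) | _closure(pred, node) | {node})


def log_subgraph_adjust(S, n_sg):
    """f(S_n) = S_n / max(1, ln N_SG_n): deflate importance of nodes with a
    large reachable subgraph; the clamp keeps tiny subgraphs (N_SG < e)
    from being amplified."""
    return np.asarray(S, dtype=float) / np.maximum(
        1.0, np.log(np.asarray(n_sg, dtype=float)))


def degree_threshold_adjust(S, d_tot, mu, sigma):
    """f(S_n) = S_n / d_tot_n only where d_tot_n > mu + 5 sigma, else S_n."""
    S = np.asarray(S, dtype=float)
    d = np.asarray(d_tot, dtype=float)
    return np.where(d > mu + 5 * sigma, S / d, S)


def adjust(table: pd.DataFrame, spec: LayeredSpec,
           method: str = "log_subgraph") -> pd.DataFrame:
    """Connectivity-corrected importances.

    ``log_subgraph`` (default): f(S_n) = S_n / max(1, ln N_SG_n).
    ``degree_threshold``: f(S_n) = S_n / d_tot_n where d_tot_n > mu + 5 sigma,
    else S_n.  ``none``: identity.  Adds ``N_SG``, ``d_tot``, per-class
    ``adjusted__<class>`` columns and the class-mean ``adjusted``.
    """
    if method not in ("log_subgraph", "degree_threshold", "none"):
        raise ValueError(f"unknown adjustment method {method!r}")
    out = table.copy()
    adj_maps = layered_adjacency(spec)
    out["N_SG"] = [subgraph_size(spec, n, _adj=adj_maps) for n in out["node"]]
    stats = degree_stats(spec)
    out["d_tot"] = [stats.d_tot[n] for n in out["node"]]
    def apply(S):
        if method == "log_subgraph":
            return log_subgraph_adjust(S, out["N_SG"])
        if method == "degree_threshold":
            return degree_threshold_adjust(S, out["d_tot"],
                                           stats.mu, stats.sigma)
        return np.asarray(S, dtype=float)

    for c in [c for c in out.columns if c.startswith("S__")]:
        out["adjusted__" + c[3:]] = apply(out[c])
    out["adjusted"] = apply(out["S"])
    return out


# ---------------------------------------------------------------------------
# Sankey export
# ---------------------------------------------------------------------------


def sankey_export(table: pd.DataFrame, spec: LayeredSpec, top_k: int = 10,
                  *, drop_unlabeled_only: bool = False) -> dict:
    """Flow data for a Sankey diagram of node importance.

    Each node's outgoing flow equals its adjusted importance, split across
    its outgoing edges proportionally to the target nodes' adjusted
    importance (equal split if all targets are zero).  The ``top_k`` nodes
    per layer (by class-mean adjusted importance) are labeled; the rest
    are pooled into one "Other connections" node per layer.  For
    multi-class models every link carries one flow value per class.
    Optionally drops pooled-only nodes that neither originate from nor
    target a labeled node.
    """
    if "adjusted" not in table.columns:
        raise ValueError("run adjust() before sankey_export()")
    classes = [c[len("adjusted__"):] for c in table.columns
               if c.startswith("adjusted__")]
    adj = table.set_index("node")
    succ, _ = layered_adjacency(spec)

    labeled: dict = {}
    for l, layer_nodes in enumerate(spec.layers[:-1]):
        sub = adj.loc[[n for n in layer_nodes]].sort_values(
            "adjusted", ascending=False)
        labeled[l] = set(sub.index[:top_k])

    def display(node: str, layer: int) -> str:
        return node if node in labeled.get(layer, set()) else f"other_l{layer}"

    def node_adjusted(node: str, col: str) -> float:
        if node in adj.index:
            return float(adj.loc[node, col])
        return 0.0  # output nodes carry no importance of their own

    links: dict = {}
    n_layers = len(spec.layers)
    for l, layer_nodes in enumerate(spec.layers[:-1]):
        for node in layer_nodes:
            targets = sorted(succ[node])
            if not targets:
                continue
            t_layer = l + 1
            for col in ["adjusted"] + [f"adjusted__{c}" for c in classes]:
                flow = node_adjusted(node, col)
                weights = np.array([
                    node_adjusted(t, col) if t_layer < n_layers - 1 else 1.0
                    for t in targets])
                if weights.sum() <= 0:
                    weights = np.ones(len(targets))
                weights = weights / weights.sum()
                for t, w in zip(targets, weights):
                    key = (display(node, l), l,
                           display(t, t_layer) if t_layer < n_layers - 1 else t)
                    rec = links.setdefault(key, {c2: 0.0 for c2 in
                                                 ["total"] + classes})
                    name = "total" if col == "adjusted" else col[len("adjusted__"):]
                    rec[name] += flow * w

    link_list = [{"source": k[0], "source_layer": k[1], "target": k[2],
                  "flow": v["total"],
                  "per_class": {c: v[c] for c in classes}}
                 for k, v in sorted(links.items())]

    incoming: dict = {}
    outgoing: dict = {}
    for lk in link_list:
        outgoing[lk["source"]] = outgoing.get(lk["source"], 0.0) + lk["flow"]
        incoming[lk["target"]] = incoming.get(lk["target"], 0.0) + lk["flow"]

    nodes = []
    for l, layer_nodes in enumerate(spec.layers):
        shown = set()
        for node in layer_nodes:
            disp = (display(node, l) if l < n_layers - 1 else node)
            if disp in shown:
                continue
            shown.add(disp)
            is_other = disp.startswith("other_l")
            total = incoming.get(disp, 0.0) + outgoing.get(disp, 0.0)
            layer_vals = adj.loc[[n for n in layer_nodes if n in adj.index],
                                 "adjusted"]
            rel = (float(adj.loc[node, "adjusted"]) / float(layer_vals.max())
                   if not is_other and node in adj.index
                   and len(layer_vals) and layer_vals.max() > 0 else 0.0)
            nodes.append({
                "id": disp, "layer": l,
                "label": ("Other connections" if is_other
                          else spec.annotations[node].label),
                "total_flow": total, "relative_importance": rel,
                "labeled": not is_other,
            })

    if drop_unlabeled_only:
        keep_ids = set()
        for lk in link_list:
            s_lab = not lk["source"].startswith("other_l")
            t_lab = not lk["target"].startswith("other_l")
            if s_lab or t_lab:
                keep_ids |= {lk["source"], lk["target"]}
        link_list = [lk for lk in link_list
                     if lk["source"] in keep_ids and lk["target"] in keep_ids
                     and not (lk["source"].startswith("other_l")
                              and lk["target"].startswith("other_l"))]
        nodes = [nd for nd in nodes if nd["id"] in keep_ids]

    return {"classes": classes, "top_k": top_k, "nodes": nodes,
            "links": link_list}


def sankey_to_json(data: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
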