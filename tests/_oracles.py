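"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written against networkx / plain
enumeration, not against the package's own graph code, so that agreement
between the two is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# Layerization oracle: backward BFS with copy padding, via networkx
# ---------------------------------------------------------------------------


def layerize_oracle(edges, protein_map, proteins, n_hidden, n_classes=1):
    """Reference layerization: returns (layers, edge_set) or None if empty.

    ``edges`` are (child, parent) pathway relations; ``protein_map`` must
    carry all-levels memberships.  Nodes are assigned to the layer given
    by shortest distance from a virtual output attached to every root;
    pathways without a predecessor in the adjacent lower layer are padded
    to L1 with copy chains; only nodes on a complete protein->output path
    survive.
    """
    g = nx.DiGraph()
    g.add_edges_from(edges)  # child -> parent

    # upward closure from the proteins' pathways
    seeds = set()
    for p in proteins:
        seeds |= {pw for pw in protein_map.get(p, ()) if pw in g}
    keep = set(seeds)
    for s in seeds:
        keep |= nx.descendants(g, s)  # descendants along child->parent = ancestors
    sub = g.subgraph(keep).copy()
    roots = {n for n in sub if sub.out_degree(n) == 0}
    if not roots:
        return None

    # distance from the virtual output
    aug = sub.copy()
    aug.add_node("__out__")
    for r in roots:
        aug.add_edge(r, "__out__")
    dist = nx.single_source_shortest_path_length(aug.reverse(), "__out__")
    layer = {v: n_hidden + 1 - d for v, d in dist.items()
             if v != "__out__" and d <= n_hidden}

    # build the candidate layered digraph, with copy chains
    net = nx.DiGraph()
    source = {}
    for v, l in layer.items():
        net.add_node((v, l))
        source[(v, l)] = v
    for c, p in sub.edges():
        if c in layer and p in layer and layer[p] == layer[c] + 1:
            net.add_edge((c, layer[c]), (p, layer[p]))
    for v, l in sorted(layer.items()):
        has_adjacent = any(layer.get(c) == l - 1
                           for c in sub.predecessors(v))
        if l > 1 and not has_adjacent:
            above = (v, l)
            for cl in range(l - 1, 0, -1):
                cid = (f"{v}__copy_l{cl}", cl)
                net.add_node(cid)
                source[cid] = v
                net.add_edge(cid, above)
                above = cid
    for k in range(n_classes):
        net.add_node(("__output__", k))
    for v, l in layer.items():
        if l == n_hidden:
            for k in range(n_classes):
                net.add_edge((v, l), ("__output__", k))
    for p in sorted(proteins):
        targets = [n for n in net.nodes
                   if n[0] != "__output__" and isinstance(n[1], int)
                   and n[1] == 1 and source.get(n) in protein_map.get(p, set())]
        if targets:
            net.add_node(("__prot__", p))
            for t in targets:
                net.add_edge(("__prot__", p), t)

    # survival: on a path from a protein to the output
    prots = [n for n in net if n[0] == "__prot__"]
    outs = [n for n in net if n[0] == "__output__"]
    fwd = set()
    for p in prots:
        fwd |= nx.descendants(net, p) | {p}
    bwd = set(outs)
    rev = net.reverse()
    for o in outs:
        bwd |= nx.descendants(rev, o)
    alive = fwd & bwd
    net = net.subgraph(alive)
    if not any(n[0] == "__prot__" for n in net):
        return None

    def name(n):
        if n[0] == "__prot__":
            return n[1]
        if n[0] == "__output__":
            return f"output_{n[1]}"
        return n[0]

    def sort_key(nm):
        if "__copy_l" in nm:
            return (nm.split("__copy_l")[0], True, nm)
        return (nm, False, nm)

    layers = [sorted(name(n) for n in net if n[0] == "__prot__")]
    for l in range(1, n_hidden + 1):
        nodes = [n for n in net
                 if n[0] not in ("__prot__", "__output__") and n[1] == l]
        layers.append(sorted((name(n) for n in nodes), key=sort_key))
    layers.append([f"output_{k}" for k in range(n_classes)])
    edge_set = {(name(u), name(v)) for u, v in net.edges()}
    return layers, edge_set


def spec_edge_set(spec):
    """Flatten a LayeredSpec's masks into a set of (src, dst) node pairs."""
    out = set()
    for i, m in enumerate(spec.masks):
        for a, b in zip(*np.nonzero(m)):
            out.add((spec.layers[i][a], spec.layers[i + 1][b]))
    return out


def all_path_lengths(spec):
    """Lengths of every input->output path, by explicit DFS over the masks."""
    g = nx.DiGraph(spec_edge_set(spec))
    lengths = set()
    outputs = set(spec.layers[-1])
    for p in spec.layers[0]:
        for o in outputs:
            if nx.has_path(g, p, o):
                for path in nx.all_simple_paths(g, p, o):
                    lengths.add(len(path) - 1)
    return lengths


# ---------------------------------------------------------------------------
# Reachability / subgraph oracles
# ---------------------------------------------------------------------------


def reachability_oracle(spec, node, direction):
    g = nx.DiGraph(spec_edge_set(spec))
    g.add_nodes_from(n for layer in spec.layers for n in layer)
    down = nx.descendants(g, node) | {node}
    up = nx.ancestors(g, node) | {node}
    if direction == "downstream":
        return down
    if direction == "upstream":
        return up
    return down | up


def subgraph_size_oracle(spec, node):
    return len(reachability_oracle(spec, node, "complete"))


# ---------------------------------------------------------------------------
# Metric oracles
# ---------------------------------------------------------------------------


def rand_index_oracle(a, b):
    """Pair-counting Rand index over all unordered sample pairs."""
    a, b = list(a), list(b)
    agree = total = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        total += 1
        if (a[i] == a[j]) == (b[i] == b[j]):
            agree += 1
    return agree / total


def roc_auc_oracle(y, scores):
    """AUC by enumerating all positive/negative pairs (ties count 1/2)."""
    pos = [s for yy, s in zip(y, scores) if yy == 1]
    neg = [s for yy, s in zip(y, scores) if yy == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def two_stage_bh_oracle(pvals, alpha=0.05):
    """Two-stage step-up FDR adjustment, from the procedure's definition.

    Stage 1 runs Benjamini-Hochberg step-up at level alpha/(1+alpha) to
    estimate the number of true nulls m0 = m - r1; stage 2 rescales the
    ordinary BH-adjusted p-values by m0/m.
    """
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)

    def bh_adj(pv):
        adj = pv[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        return out

    alpha1 = alpha / (1 + alpha)
    r1 = int((bh_adj(p) <= alpha1).sum())
    m0 = m - r1
    if r1 in (0, m):
        return bh_adj(p)  # second stage is skipped at the extremes
    return np.minimum(bh_adj(p) * m0 / m, 1.0)
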