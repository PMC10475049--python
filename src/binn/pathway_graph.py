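"""Pathway hierarchies and their compilation into layered sparse-network specs.

A pathway hierarchy (e.g. the Reactome relation file) is a DAG of
child → parent edges whose roots (out-degree 0 in the child→parent
direction) are high-level biological processes.  Together with a
protein → pathway membership table it is compiled, for a given protein
list, into a :class:`LayeredSpec`: an ordered sequence of node layers and
binary connectivity masks that define a sparse sequential neural network.

The compilation follows a backward traversal from a virtual output node:

1. subset the hierarchy to the ancestor closure of the pathways the
   proteins map to;
2. attach an output node to every root;
3. walk backwards ``n_hidden`` layers, assigning each pathway to the layer
   given by its shortest distance from the output;
4. pad pathways that run out of predecessors before the first hidden
   layer with chains of pass-through *copy* nodes;
5. drop pathways the traversal never reached, and connect each protein to
   the first-hidden-layer nodes whose source pathway it maps to.

Every input → output path in the result has exactly ``n_hidden + 1`` edges.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "LayeredSpec",
    "NodeAnnotation",
    "DegreeStats",
    "parse_hierarchy",
    "parse_mapping",
    "load_graph",
    "subset_graph",
    "layerize",
    "count_edges",
    "degree_stats",
]


class GraphError(ValueError):
    """Malformed hierarchy/mapping input or an invalid graph operation."""


# ---------------------------------------------------------------------------
# PathwayGraph
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PathwayGraph:
    """A pathway DAG plus protein memberships.

    Parameters
    ----------
    edges
        Set of ``(child_id, parent_id)`` pathway relations.
    protein_map
        Mapping ``protein_id -> frozenset of pathway ids`` (ideally at all
        hierarchy levels, as in Reactome's *All_Levels* mapping files).
    node_names
        Optional ``id -> human readable label``.
    unmapped_proteins
        Proteins whose every pathway is absent from the hierarchy; kept for
        the discard report.
    """

    edges: frozenset = frozenset()
    protein_map: Mapping[str, frozenset] = field(default_factory=dict)
    node_names: Mapping[str, str] = field(default_factory=dict)
    unmapped_proteins: tuple = ()

    def __post_init__(self):
        _check_acyclic(self.edges)

    @property
    def nodes(self) -> set:
        out = set()
        for c, p in self.edges:
            out.add(c)
            out.add(p)
        return out

    @property
    def roots(self) -> set:
        """Pathways with out-degree 0 in the child→parent direction."""
        children = {c for c, _ in self.edges}
        return self.nodes - children

    def parent_to_children(self) -> dict:
        adj: dict = {}
        for c, p in self.edges:
            adj.setdefault(p, set()).add(c)
        return adj

    def label(self, node: str) -> str:
        return self.node_names.get(node, node)


def _check_acyclic(edges: Iterable) -> None:
    ts = TopologicalSorter()
    for child, parent in edges:
        if child == parent:
            raise GraphError(f"self-loop on node {child!r}")
        ts.add(parent, child)  # parent depends on child
    try:
        ts.prepare()
    except CycleError as exc:
        raise GraphError(f"hierarchy contains a cycle: {exc.args[1]}") from exc


def _open_text(path):
    data = open(path, "rb").read()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return io.StringIO(data.decode())


def _read_tsv_pairs(path, col_a: int, col_b: int, header: bool):
    """Yield (value_a, value_b, line_number) from a two-plus-column TSV."""
    need = max(col_a, col_b) + 1
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n\r")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < need:
                raise GraphError(
                    f"{path}: line {lineno}: expected >= {need} tab-separated "
                    f"columns, got {len(parts)}"
                )
            a, b = parts[col_a].strip(), parts[col_b].strip()
            if not a or not b:
                raise GraphError(f"{path}: line {lineno}: empty identifier")
            yield a, b, lineno


def parse_hierarchy(path, child_col: int = 1, parent_col: int = 0,
                    header: bool = False) -> PathwayGraph:
    """Parse a pathway relation TSV into a :class:`PathwayGraph` (edges only).

    Reactome distributes relation files as ``(parent, child)`` rows; the
    defaults read that dialect and store edges in the child→parent
    direction.  Duplicate rows are deduplicated; self-loops and cycles are
    rejected.
    """
    edges = set()
    for child, parent, lineno in _read_tsv_pairs(path, child_col, parent_col, header):
        if child == parent:
            raise GraphError(f"{path}: line {lineno}: self-loop on {child!r}")
        edges.add((child, parent))
    if not edges:
        raise GraphError(f"{path}: no hierarchy edges found")
    return PathwayGraph(edges=frozenset(edges))


def parse_mapping(path, protein_col: int = 0, pathway_col: int = 1,
                  header: bool = False) -> dict:
    """Parse a protein→pathway membership TSV into ``{protein: set(pathways)}``."""
    mapping: dict = {}
    for prot, pw, _ in _read_tsv_pairs(path, protein_col, pathway_col, header):
        mapping.setdefault(prot, set()).add(pw)
    if not mapping:
        raise GraphError(f"{path}: no protein-pathway rows found")
    return mapping


def load_graph(hierarchy_path, mapping_path, *, child_col: int = 1,
               parent_col: int = 0, protein_col: int = 0, pathway_col: int = 1,
               header: bool = False, names: Mapping[str, str] | None = None,
               ) -> PathwayGraph:
    """Parse both Reactome-dialect files and combine them.

    Proteins whose every membership refers to a pathway absent from the
    hierarchy are recorded in ``unmapped_proteins`` (the discard report);
    their dangling memberships are dropped.
    """
    g = parse_hierarchy(hierarchy_path, child_col, parent_col, header)
    raw_map = parse_mapping(mapping_path, protein_col, pathway_col, header)
    nodes = g.nodes
    protein_map, unmapped = {}, []
    for prot, pws in sorted(raw_map.items()):
        kept = frozenset(pw for pw in pws if pw in nodes)
        if kept:
            protein_map[prot] = kept
        else:
            unmapped.append(prot)
    if unmapped:
        logger.info("%d protein(s) map to no pathway of the hierarchy: %s",
                    len(unmapped), ", ".join(unmapped[:10]))
    return PathwayGraph(edges=g.edges, protein_map=protein_map,
                        node_names=dict(names or {}),
                        unmapped_proteins=tuple(unmapped))


# ---------------------------------------------------------------------------
# Subsetting
# ---------------------------------------------------------------------------


def subset_graph(graph: PathwayGraph, proteins: Sequence[str]) -> PathwayGraph:
    """Restrict the hierarchy to the upward closure of the given proteins.

    Keeps exactly the pathways reachable in the child→parent direction from
    the pathways the proteins map to, up to the roots.  Proteins with no
    retained pathway are dropped (counted in the log).
    """
    proteins = list(proteins)
    mapped = {p: graph.protein_map.get(p, frozenset()) for p in proteins}
    seeds = set().union(*mapped.values()) if mapped else set()
    seeds &= graph.nodes
    if not seeds:
        raise GraphError(
            "none of the supplied proteins map to a pathway of the hierarchy; "
            "the whole protein list would be discarded in the analysis")

    parents: dict = {}
    for c, p in graph.edges:
        parents.setdefault(c, set()).add(p)
    keep = set(seeds)
    frontier = list(seeds)
    while frontier:
        node = frontier.pop()
        for par in parents.get(node, ()):
            if par not in keep:
                keep.add(par)
                frontier.append(par)

    edges = frozenset((c, p) for c, p in graph.edges if c in keep and p in keep)
    protein_map, dropped = {}, 0
    for p in proteins:
        kept = frozenset(pw for pw in mapped[p] if pw in keep)
        if kept:
            protein_map[p] = kept
        else:
            dropped += 1
    if dropped:
        logger.info("subset_graph: %d protein(s) retained no pathway and were "
                    "dropped", dropped)
    return PathwayGraph(edges=edges, protein_map=protein_map,
                        node_names=graph.node_names,
                        unmapped_proteins=graph.unmapped_proteins)


def expand_mapping_to_ancestors(graph: PathwayGraph) -> PathwayGraph:
    """Extend a flat (lowest-level) mapping by ancestor closure.

    Use when the mapping file lists only each protein's most specific
    pathway; the layered network's protein attachment assumes all-levels
    membership semantics.
    """
    parents: dict = {}
    for c, p in graph.edges:
        parents.setdefault(c, set()).add(p)

    def closure(pws):
        out = set(pws)
        frontier = list(pws)
        while frontier:
            node = frontier.pop()
            for par in parents.get(node, ()):
                if par not in out:
                    out.add(par)
                    frontier.append(par)
        return frozenset(out)

    expanded = {p: closure(pws) for p, pws in graph.protein_map.items()}
    logger.info("expanded flat mapping by ancestor closure for %d proteins",
                len(expanded))
    return PathwayGraph(edges=graph.edges, protein_map=expanded,
                        node_names=graph.node_names,
                        unmapped_proteins=graph.unmapped_proteins)


# ---------------------------------------------------------------------------
# LayeredSpec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeAnnotation:
    """Provenance of one layered-network node."""

    id: str
    source: str          # originating protein/pathway id ("output" for outputs)
    label: str
    is_copy: bool = False
    copy_of: str | None = None


@dataclass
class LayeredSpec:
    """A layerized pathway network: ordered node layers plus binary masks.

    ``layers[0]`` holds the proteins, ``layers[1..n_hidden]`` pathway nodes
    (possibly pass-through copies) and ``layers[n_hidden + 1]`` the
    ``n_classes`` output node(s).  ``masks[i]`` is a ``len(layers[i]) x
    len(layers[i+1])`` 0/1 matrix; entry ``[j, k]`` connects node ``j`` of
    layer ``i`` to node ``k`` of layer ``i+1``.
    """

    n_hidden: int
    n_classes: int
    layers: list          # list of list[str] node ids
    masks: list           # list of np.ndarray (uint8)
    annotations: dict     # node id -> NodeAnnotation

    SCHEMA_VERSION = 1

    # -- basic queries ------------------------------------------------------

    @property
    def proteins(self) -> list:
        return list(self.layers[0])

    def layer_of(self, node: str) -> int:
        for i, layer in enumerate(self.layers):
            if node in layer:
                return i
        raise KeyError(f"unknown node {node!r}")

    def validate(self) -> None:
        if len(self.masks) != self.n_hidden + 1:
            raise GraphError("mask count does not match layer count")
        for i, m in enumerate(self.masks):
            if m.shape != (len(self.layers[i]), len(self.layers[i + 1])):
                raise GraphError(f"mask {i} shape {m.shape} does not match layers")
            if m.sum() == 0:
                raise GraphError(f"mask {i} is empty: no surviving connectivity")

    def successors(self, node: str) -> set:
        i = self.layer_of(node)
        if i == len(self.layers) - 1:
            return set()
        j = self.layers[i].index(node)
        nxt = np.nonzero(self.masks[i][j])[0]
        return {self.layers[i + 1][k] for k in nxt}

    def predecessors(self, node: str) -> set:
        i = self.layer_of(node)
        if i == 0:
            return set()
        j = self.layers[i].index(node)
        prev = np.nonzero(self.masks[i - 1][:, j])[0]
        return {self.layers[i - 1][k] for k in prev}

    # -- serialization ------------------------------------------------------

    def to_json(self, path=None) -> str:
        doc = {
            "schema_version": self.SCHEMA_VERSION,
            "n_hidden": self.n_hidden,
            "n_classes": self.n_classes,
            "layers": self.layers,
            "masks": [
                [[int(a), int(b)] for a, b in zip(*np.nonzero(m))]
                for m in self.masks
            ],
            "annotations": {
                nid: {"source": a.source, "label": a.label,
                      "is_copy": a.is_copy, "copy_of": a.copy_of}
                for nid, a in sorted(self.annotations.items())
            },
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "LayeredSpec":
        if hasattr(source, "read"):
            doc = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        layers = [list(l) for l in doc["layers"]]
        masks = []
        for i, pairs in enumerate(doc["masks"]):
            m = np.zeros((len(layers[i]), len(layers[i + 1])), dtype=np.uint8)
            for a, b in pairs:
                m[a, b] = 1
            masks.append(m)
        anns = {
            nid: NodeAnnotation(id=nid, source=a["source"], label=a["label"],
                                is_copy=a["is_copy"], copy_of=a["copy_of"])
            for nid, a in doc["annotations"].items()
        }
        spec = cls(n_hidden=doc["n_hidden"], n_classes=doc["n_classes"],
                   layers=layers, masks=masks, annotations=anns)
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# Layerization
# ---------------------------------------------------------------------------


def _copy_id(source: str, layer: int) -> str:
    return f"{source}__copy_l{layer}"


def layerize(graph: PathwayGraph, proteins: Sequence[str], n_hidden: int,
             n_classes: int = 1, *, expand_flat_mapping: bool = False,
             ) -> LayeredSpec:
    """Compile a pathway DAG into a fixed-depth layered network spec.

    Each pathway is assigned to the single layer given by its shortest
    backward distance from the output; pathways whose predecessors do not
    continue into the adjacent lower layer are padded toward the input with
    chains of copy nodes, so that every path from protein to output has
    exactly ``n_hidden + 1`` edges.  Pathway nodes never reached within
    ``n_hidden`` steps, and nodes left without protein support, are removed.
    """
    if n_hidden < 1:
        raise GraphError("n_hidden must be >= 1")
    if not proteins:
        raise GraphError("protein list is empty")
    if n_classes < 1:
        raise GraphError("n_classes must be >= 1")
    if expand_flat_mapping:
        graph = expand_mapping_to_ancestors(graph)
    g = subset_graph(graph, proteins)

    # backward BFS from the virtual output: roots at distance 1
    children = g.parent_to_children()
    dist = {r: 1 for r in sorted(g.roots)}
    frontier = sorted(g.roots)
    while frontier:
        nxt = []
        for node in frontier:
            if dist[node] >= n_hidden:
                continue
            for ch in children.get(node, ()):
                if ch not in dist:
                    dist[ch] = dist[node] + 1
                    nxt.append(ch)
        frontier = sorted(set(nxt))

    layer_of = {v: n_hidden + 1 - d for v, d in dist.items()}  # hidden index 1..N

    # per-layer membership of original pathways
    members: list = [set() for _ in range(n_hidden + 2)]
    for v, l in layer_of.items():
        members[l].add(v)

    # copy chains: a pathway with no retained predecessor in the layer below
    # behaves like a terminal and is extended to L1 with pass-through copies
    copies: dict = {}            # copy id -> (source, layer)
    chain_bottom: dict = {}      # pathway -> node id receiving protein fan-in
    extra_edges = set()          # (child_node_id, parent_node_id) among hidden
    for v in sorted(layer_of):
        l = layer_of[v]
        adj_children = {c for c in children.get(v, ()) if layer_of.get(c) == l - 1}
        if l == 1:
            chain_bottom[v] = v
        elif not adj_children:
            below = v
            for cl in range(l - 1, 0, -1):
                cid = _copy_id(v, cl)
                copies[cid] = (v, cl)
                members[cl].add(cid)
                extra_edges.add((cid, below))
                below = cid
            chain_bottom[v] = below

    def source_of(node: str) -> str:
        return copies[node][0] if node in copies else node

    # protein attachment: protein -> L1 nodes whose source pathway it maps to
    l1_by_source: dict = {}
    for node in members[1]:
        l1_by_source.setdefault(source_of(node), set()).add(node)
    protein_edges: dict = {}
    dropped = 0
    for p in sorted(g.protein_map):
        targets = set()
        for pw in g.protein_map[p]:
            targets |= l1_by_source.get(pw, set())
        if targets:
            protein_edges[p] = targets
        else:
            dropped += 1
    if dropped:
        logger.info("layerize: %d protein(s) have no membership at the first "
                    "hidden layer and were dropped", dropped)
    if not protein_edges:
        raise GraphError("no protein connects to the first hidden layer; "
                         "an all-levels mapping (or expand_flat_mapping=True) "
                         "is required for this depth")

    # hidden-to-hidden edges: DAG edges between adjacent layers, plus chains
    hidden_edges = set(extra_edges)
    for c, p in g.edges:
        if layer_of.get(c) is not None and layer_of.get(p) == layer_of.get(c) + 1:
            hidden_edges.add((c, p))

    # prune nodes without input support or without a path to the output,
    # iterating to a fixed point (removals can cascade in both directions)
    changed = True
    while changed:
        changed = False
        for l in range(1, n_hidden + 1):
            for node in sorted(members[l]):
                if l == 1:
                    has_in = any(node in ts for ts in protein_edges.values())
                else:
                    has_in = any(p == node and c in members[l - 1]
                                 for c, p in hidden_edges)
                if l == n_hidden:
                    has_out = True  # top hidden layer feeds the output node(s)
                else:
                    has_out = any(c == node and p in members[l + 1]
                                  for c, p in hidden_edges)
                if not (has_in and has_out):
                    members[l].discard(node)
                    hidden_edges = {(c, p) for c, p in hidden_edges
                                    if c != node and p != node}
                    changed = True
    protein_edges = {p: {t for t in ts if t in members[1]}
                     for p, ts in protein_edges.items()}
    protein_edges = {p: ts for p, ts in protein_edges.items() if ts}
    if not protein_edges or not members[n_hidden]:
        raise GraphError("pruning removed all protein connections")

    # deterministic ordering: lexicographic by source id, copies after originals
    def node_key(node: str):
        return (source_of(node), node in copies, node)

    layers = [sorted(protein_edges)]
    for l in range(1, n_hidden + 1):
        layers.append(sorted(members[l], key=node_key))
    out_nodes = [f"output_{k}" for k in range(n_classes)]
    layers.append(out_nodes)

    # masks
    masks = []
    index = [{n: j for j, n in enumerate(layer)} for layer in layers]
    m0 = np.zeros((len(layers[0]), len(layers[1])), dtype=np.uint8)
    for p, targets in protein_edges.items():
        for t in targets:
            m0[index[0][p], index[1][t]] = 1
    masks.append(m0)
    for l in range(1, n_hidden):
        m = np.zeros((len(layers[l]), len(layers[l + 1])), dtype=np.uint8)
        for c, p in hidden_edges:
            if c in index[l] and p in index[l + 1]:
                m[index[l][c], index[l + 1][p]] = 1
        masks.append(m)
    m_out = np.ones((len(layers[n_hidden]), n_classes), dtype=np.uint8)
    masks.append(m_out)

    annotations = {}
    for p in layers[0]:
        annotations[p] = NodeAnnotation(id=p, source=p, label=graph.label(p))
    for l in range(1, n_hidden + 1):
        for node in layers[l]:
            src = source_of(node)
            annotations[node] = NodeAnnotation(
                id=node, source=src, label=graph.label(src),
                is_copy=node in copies, copy_of=src if node in copies else None)
    for o in out_nodes:
        annotations[o] = NodeAnnotation(id=o, source="output", label=o)

    spec = LayeredSpec(n_hidden=n_hidden, n_classes=n_classes, layers=layers,
                       masks=masks, annotations=annotations)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Spec statistics
# ---------------------------------------------------------------------------


def count_edges(spec: LayeredSpec) -> dict:
    """Mask popcounts per layer interface.

    Returns per-interface weight counts, the total, the hidden-interface
    total (connections strictly between hidden layers, the figure quoted
    for model sparsity), and bias counts so that either parameter-counting
    convention can be compared.
    """
    spec.validate()
    per_interface = [int(m.sum()) for m in spec.masks]
    hidden_total = int(sum(per_interface[1:-1]))
    biases = [len(layer) for layer in spec.layers[1:]]
    return {
        "per_interface": per_interface,
        "total_weights": int(sum(per_interface)),
        "hidden_total": hidden_total,
        "biases_per_layer": biases,
        "total_biases": int(sum(biases)),
    }


@dataclass(frozen=True)
class DegreeStats:
    """In/out/total degree per node of the layered network, with μ and σ of
    the total degree over all nodes (inputs and outputs included)."""

    d_in: Mapping[str, int]
    d_out: Mapping[str, int]
    d_tot: Mapping[str, int]
    mu: float
    sigma: float


def degree_stats(spec: LayeredSpec) -> DegreeStats:
    d_in: dict = {}
    d_out: dict = {}
    for i, layer in enumerate(spec.layers):
        for j, node in enumerate(layer):
            din = int(spec.masks[i - 1][:, j].sum()) if i > 0 else 0
            dout = int(spec.masks[i][j].sum()) if i < len(spec.masks) else 0
            d_in[node] = din
            d_out[node] = dout
    d_tot = {n: d_in[n] + d_out[n] for n in d_in}
    vals = np.array(list(d_tot.values()), dtype=float)
    return DegreeStats(d_in=d_in, d_out=d_out, d_tot=d_tot,
                       mu=float(vals.mean()), sigma=float(vals.std()))
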