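"""The expanded graph: a per-haplotype duplicated, weighted DAG.

Each haplotype path of the pangenome graph becomes its own chain of vertices
between a shared source ``s`` and sink ``t``.  Weight-0 edges connect
consecutive chain vertices and the chain termini to s/t; weighted cross edges
model *useful* recombinations — haplotype switches at positions where staying
on the current haplotype cannot follow the desired edge.  An inferred path of
the original graph corresponds to a unit s→t flow here, with total edge
weight c·gamma.

Two constructions are provided:

* :func:`build_naive` — one weight-``c`` edge per (source chain position,
  target chain position) pair, O(|H|^2) edges per recombination site;
* :func:`build_optimized` — an intermediate epsilon-labeled vertex ``w_e``
  per graph edge ``e`` allowing a recombination, with weight ``c/2`` edges in
  and out, O(|H|) edges per site.  The set of chain-to-chain moves reachable
  through exactly one ``w_e`` equals the naive edge set, so both give the
  same optima.

Preprocessing helpers :func:`split_long_labels` (enforce the label-length
bound required by the hit definition) and :func:`split_edges_with_epsilon`
(insert an epsilon vertex in the middle of every edge so that a switch "on an
edge" has a vertex to land on) operate on the pangenome graph itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph_model import (
    GraphValidationError,
    HaplotypePath,
    PangenomeGraph,
)

SOURCE = "s"
SINK = "t"


@dataclass
class ExpandedGraph:
    """Weighted expanded DAG GE(VE, EE, sigmaE).

    ``chains[j]`` lists the chain vertex ids of haplotype ``j`` in order.
    ``origin`` maps a chain vertex to (original vertex, haplotype j,
    1-based position i); ``w_e`` vertices map to the original edge via
    ``edge_vertex_origin``.
    """

    labels: dict[str, str]
    edges: dict[tuple[str, str], float]
    chains: list[list[str]]
    origin: dict[str, tuple[str, int, int]]
    edge_vertex_origin: dict[str, tuple[str, str]] = field(default_factory=dict)
    penalty: float = 0.0
    graph: PangenomeGraph | None = None

    _out: dict[str, tuple[str, ...]] | None = field(default=None, repr=False)
    _in: dict[str, tuple[str, ...]] | None = field(default=None, repr=False)

    @property
    def source(self) -> str:
        return SOURCE

    @property
    def sink(self) -> str:
        return SINK

    def _build_adj(self) -> None:
        out: dict[str, list[str]] = {v: [] for v in self.labels}
        inn: dict[str, list[str]] = {v: [] for v in self.labels}
        for u, v in sorted(self.edges):
            out[u].append(v)
            inn[v].append(u)
        self._out = {v: tuple(ws) for v, ws in out.items()}
        self._in = {v: tuple(ws) for v, ws in inn.items()}

    def out_neighbors(self, u: str) -> tuple[str, ...]:
        if u not in self.labels:
            raise KeyError(f"unknown expanded-graph vertex {u!r}")
        if self._out is None:
            self._build_adj()
        return self._out[u]  # type: ignore[index]

    def in_neighbors(self, u: str) -> tuple[str, ...]:
        if u not in self.labels:
            raise KeyError(f"unknown expanded-graph vertex {u!r}")
        if self._in is None:
            self._build_adj()
        return self._in[u]  # type: ignore[index]

    def recombination_edges(self) -> dict[tuple[str, str], float]:
        return {e: w for e, w in self.edges.items() if w != 0.0}

    def to_dot(self) -> str:
        """DOT export for eyeballing small graphs."""
        lines = ["digraph GE {"]
        for v, lab in sorted(self.labels.items()):
            lines.append(f'  "{v}" [label="{v}\\n{lab or "eps"}"];')
        for (u, v), w in sorted(self.edges.items()):
            style = ' [color=purple, label="%g"]' % w if w else ""
            lines.append(f'  "{u}" -> "{v}"{style};')
        lines.append("}")
        return "\n".join(lines)


def neighborhoods(eg: ExpandedGraph, u: str) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """(N+(u), N-(u)): out- and in-neighbor sets of ``u`` in GE."""
    return eg.out_neighbors(u), eg.in_neighbors(u)


# ---------------------------------------------------------------------- #
# preprocessing on the pangenome graph


def split_long_labels(graph: PangenomeGraph, max_len: int) -> PangenomeGraph:
    """Chain-split every vertex whose label exceeds ``max_len`` characters.

    Split parts inherit exactly the haplotypes of the original vertex and the
    spell of every haplotype path is unchanged.  Needed so that every vertex
    label is shorter than every query string (hit semantics).
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if all(len(lab) <= max_len for lab in graph.labels.values()):
        return graph

    labels: dict[str, str] = {}
    part_of: dict[str, list[str]] = {}
    for v, lab in graph.labels.items():
        if len(lab) <= max_len:
            labels[v] = lab
            part_of[v] = [v]
        else:
            parts = [lab[i : i + max_len] for i in range(0, len(lab), max_len)]
            ids = [f"{v}.{k}" for k in range(len(parts))]
            for pid, p in zip(ids, parts):
                labels[pid] = p
            part_of[v] = ids

    def expand(vs: tuple[str, ...]) -> tuple[str, ...]:
        out: list[str] = []
        for v in vs:
            out.extend(part_of[v])
        return tuple(out)

    edges: set[tuple[str, str]] = set()
    for u, v in graph.edges:
        edges.add((part_of[u][-1], part_of[v][0]))
    for v, ids in part_of.items():
        edges.update(zip(ids, ids[1:]))

    haplotypes = [
        HaplotypePath(index=h.index, vertices=expand(h.vertices), name=h.name)
        for h in graph.haplotypes
    ]
    eps = {p for v in graph.epsilon_vertices for p in part_of[v]}
    out = PangenomeGraph(
        labels=labels, edges=edges, haplotypes=haplotypes, epsilon_vertices=eps
    )
    out.validate()
    return out


def split_edges_with_epsilon(graph: PangenomeGraph) -> PangenomeGraph:
    """Insert an epsilon-labeled vertex in the middle of every edge.

    The new vertex inherits the haplotype paths supporting the edge.  This
    gives a haplotype switch taking edge (u, v) a landing vertex that belongs
    to the supporting haplotypes, preventing bogus self-recombinations in the
    expanded graph.
    """
    labels = dict(graph.labels)
    eps = set(graph.epsilon_vertices)
    mid: dict[tuple[str, str], str] = {}
    edges: set[tuple[str, str]] = set()
    for u, v in sorted(graph.edges):
        m = f"({u}~{v})"
        if m in labels:
            raise GraphValidationError(f"epsilon vertex id collision: {m!r}")
        labels[m] = ""
        eps.add(m)
        mid[(u, v)] = m
        edges.add((u, m))
        edges.add((m, v))

    haplotypes = []
    for h in graph.haplotypes:
        vs: list[str] = [h.vertices[0]]
        for u, v in zip(h.vertices, h.vertices[1:]):
            vs.append(mid[(u, v)])
            vs.append(v)
        haplotypes.append(HaplotypePath(index=h.index, vertices=tuple(vs), name=h.name))

    out = PangenomeGraph(
        labels=labels, edges=edges, haplotypes=haplotypes, epsilon_vertices=eps
    )
    out.validate()
    return out


def preprocess(
    graph: PangenomeGraph,
    min_query_length: int | None = None,
    edge_split: bool = True,
) -> PangenomeGraph:
    """Standard preprocessing: label splitting, then epsilon edge splitting.

    ``min_query_length`` is min_r |r| of the query set; labels are split to
    at most ``min_query_length - 1`` characters.
    """
    g = graph
    if min_query_length is not None:
        if min_query_length < 2:
            raise ValueError("query strings must have length >= 2")
        g = split_long_labels(g, min_query_length - 1)
    if edge_split:
        g = split_edges_with_epsilon(g)
    return g


# ---------------------------------------------------------------------- #
# expanded-graph construction

def _chains(graph: PangenomeGraph) -> tuple[list[list[str]], dict[str, tuple[str, int, int]]]:
    chains: list[list[str]] = []
    origin: dict[str, tuple[str, int, int]] = {}
    for h in graph.haplotypes:
        chain = []
        for i, v in enumerate(h.vertices, start=1):
            cv = f"h{h.index}.{i}"
            chain.append(cv)
            origin[cv] = (v, h.index, i)
        chains.append(chain)
    return chains, origin


def _useful_departures(graph: PangenomeGraph):
    """Yield (haplotype j, 1-based position i, graph edge e) triples where
    chain j can usefully leave its vertex at position i via e: the edge tail
    is h_j[i] and either i is the last position or h_j[i+1] differs from the
    edge head."""
    for h in graph.haplotypes:
        n = len(h)
        for i, u in enumerate(h.vertices, start=1):
            nxt = h.vertices[i] if i < n else None
            for v in graph.out_neighbors(u):
                if i == n or nxt != v:
                    yield h.index, i, (u, v)


def _landing_positions(graph: PangenomeGraph, v: str):
    """All (haplotype j, 1-based position i) chain copies of vertex ``v``."""
    for h in graph.haplotypes:
        for i, u in enumerate(h.vertices, start=1):
            if u == v:
                yield h.index, i


def _base(graph: PangenomeGraph, c: float):
    if c < 0:
        raise ValueError("recombination penalty c must be non-negative")
    chains, origin = _chains(graph)
    labels: dict[str, str] = {SOURCE: "", SINK: ""}
    edges: dict[tuple[str, str], float] = {}
    for h, chain in zip(graph.haplotypes, chains):
        for cv, v in zip(chain, h.vertices):
            labels[cv] = graph.labels[v]
        edges[(SOURCE, chain[0])] = 0.0
        edges[(chain[-1], SINK)] = 0.0
        for a, b in zip(chain, chain[1:]):
            edges[(a, b)] = 0.0
    return chains, origin, labels, edges


def build_naive(graph: PangenomeGraph, c: float) -> ExpandedGraph:
    """Expanded graph with direct weight-``c`` recombination edges.

    For every useful departure (chain j leaving vertex u via graph edge
    (u, v)) and every chain copy of v, one edge of weight c is created.
    """
    chains, origin, labels, edges = _base(graph, c)
    pos_index: dict[str, list[tuple[int, int]]] = {}
    for h in graph.haplotypes:
        for i, u in enumerate(h.vertices, start=1):
            pos_index.setdefault(u, []).append((h.index, i))

    for j, i, (u, v) in _useful_departures(graph):
        src = chains[j][i - 1]
        for j2, i2 in pos_index.get(v, ()):
            edges[(src, chains[j2][i2 - 1])] = float(c)

    eg = ExpandedGraph(
        labels=labels, edges=edges, chains=chains, origin=origin,
        penalty=float(c), graph=graph,
    )
    return eg


def build_optimized(graph: PangenomeGraph, c: float) -> ExpandedGraph:
    """Expanded graph with intermediate ``w_e`` vertices and c/2 edges.

    Per graph edge ``e = (u, v)`` that admits at least one useful departure,
    a vertex ``w_e`` is added with weight-c/2 edges from every usefully
    departing chain copy of ``u`` and weight-c/2 edges to every chain copy of
    ``v``.  Isolated ``w_e`` vertices are dropped.  Halving ``c`` is exact in
    double precision for any integer penalty.
    """
    chains, origin, labels, edges = _base(graph, c)
    pos_index: dict[str, list[tuple[int, int]]] = {}
    for h in graph.haplotypes:
        for i, u in enumerate(h.vertices, start=1):
            pos_index.setdefault(u, []).append((h.index, i))

    half = float(c) / 2.0
    edge_vertex_origin: dict[str, tuple[str, str]] = {}
    w_in: dict[tuple[str, str], list[str]] = {}
    for j, i, e in _useful_departures(graph):
        w_in.setdefault(e, []).append(chains[j][i - 1])

    for e, sources in sorted(w_in.items()):
        u, v = e
        targets = [chains[j2][i2 - 1] for j2, i2 in pos_index.get(v, ())]
        if not sources or not targets:
            continue  # would be an isolated or dead-end w_e
        wid = f"w({u}~{v})"
        labels[wid] = ""
        edge_vertex_origin[wid] = e
        for src in sources:
            edges[(src, wid)] = half
        for tgt in targets:
            edges[(wid, tgt)] = half

    eg = ExpandedGraph(
        labels=labels, edges=edges, chains=chains, origin=origin,
        edge_vertex_origin=edge_vertex_origin, penalty=float(c), graph=graph,
    )
    return eg
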