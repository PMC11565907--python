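"""Data model for haplotype-resolved pangenome DAGs.

A pangenome reference is a string-labeled directed acyclic graph G(V, E, σ, H)
in which every reference haplotype is embedded as a designated *haplotype
path*.  A candidate reconstruction of a sample genome is an *inferred path*:
an ordered list of (vertex, haplotype) steps that walks through the graph and
may switch haplotypes (a recombination) at a fixed penalty per switch.  The
objective optimised elsewhere in this package is

    Cost(P) = c * gamma(P) + #{ r in S : r is not a substring of spell(P) }

where ``gamma`` counts haplotype switches, ``S`` is a set of query strings
(k-mers or window minimizers from sequencing reads) and ``c >= 0`` is the
recombination penalty.
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field


class GraphValidationError(ValueError):
    """Raised when a pangenome graph violates a structural invariant."""


class GFAParseError(ValueError):
    """Raised on malformed GFA input; the message names the offending line."""


@dataclass(frozen=True)
class HaplotypePath:
    """One reference haplotype embedded in the graph.

    Vertex access follows the 1-based array convention ``h[i]``: use
    :meth:`at`.  ``vertices`` itself is an ordinary 0-based tuple.
    """

    index: int
    vertices: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        if len(self.vertices) < 1:
            raise GraphValidationError(
                f"haplotype path {self.name!r} has no vertices"
            )

    def __len__(self) -> int:
        return len(self.vertices)

    def at(self, i: int) -> str:
        """1-based vertex access ``h[i]`` with ``1 <= i <= len(h)``."""
        if not 1 <= i <= len(self.vertices):
            raise IndexError(f"haplotype position {i} out of range 1..{len(self)}")
        return self.vertices[i - 1]


@dataclass
class PangenomeGraph:
    """String-labeled DAG with embedded haplotype paths.

    Invariants (checked by :meth:`validate`):

    * the graph is acyclic;
    * every edge is supported by at least one haplotype path (consecutive
      traversal);
    * every consecutive pair in every haplotype path is an edge;
    * every vertex is covered by at least one haplotype path.

    Empty (epsilon) labels are permitted only for vertices introduced by the
    edge-splitting preprocessing step (``epsilon_vertices``).
    """

    labels: dict[str, str]
    edges: set[tuple[str, str]]
    haplotypes: list[HaplotypePath]
    epsilon_vertices: set[str] = field(default_factory=set)

    _haps_cache: dict[str, frozenset[int]] | None = field(
        default=None, repr=False, compare=False
    )
    _out_cache: dict[str, tuple[str, ...]] | None = field(
        default=None, repr=False, compare=False
    )

    # ------------------------------------------------------------------ #
    # accessors

    @property
    def vertices(self) -> set[str]:
        return set(self.labels)

    def label(self, v: str) -> str:
        return self.labels[v]

    def haps(self, v: str) -> frozenset[int]:
        """Set of haplotype indices whose path contains vertex ``v``."""
        if self._haps_cache is None:
            cache: dict[str, set[int]] = {v: set() for v in self.labels}
            for h in self.haplotypes:
                for u in h.vertices:
                    cache.setdefault(u, set()).add(h.index)
            self._haps_cache = {v: frozenset(s) for v, s in cache.items()}
        return self._haps_cache[v]

    def out_neighbors(self, v: str) -> tuple[str, ...]:
        if self._out_cache is None:
            adj: dict[str, list[str]] = {u: [] for u in self.labels}
            for u, w in sorted(self.edges):
                adj[u].append(w)
            self._out_cache = {u: tuple(ws) for u, ws in adj.items()}
        return self._out_cache[v]

    def invalidate_caches(self) -> None:
        self._haps_cache = None
        self._out_cache = None

    def haplotype(self, index: int) -> HaplotypePath:
        return self.haplotypes[index]

    # ------------------------------------------------------------------ #
    # validation

    def validate(self) -> None:
        for v, lab in self.labels.items():
            if lab == "" and v not in self.epsilon_vertices:
                raise GraphValidationError(
                    f"vertex {v!r} has an empty label but is not an "
                    "edge-split (epsilon) vertex"
                )
        for u, v in self.edges:
            if u not in self.labels or v not in self.labels:
                raise GraphValidationError(f"edge ({u!r},{v!r}) references unknown vertex")

        # acyclicity via topological sort
        adj: dict[str, set[str]] = {v: set() for v in self.labels}
        for u, v in self.edges:
            adj[u].add(v)
        try:
            tuple(graphlib.TopologicalSorter(adj).static_order())
        except graphlib.CycleError as exc:
            raise GraphValidationError(f"cycle detected: {exc.args[1]}") from exc

        # haplotype steps are edges; collect supported edges
        supported: set[tuple[str, str]] = set()
        for h in self.haplotypes:
            for u in h.vertices:
                if u not in self.labels:
                    raise GraphValidationError(
                        f"haplotype {h.name!r} visits unknown vertex {u!r}"
                    )
            for u, v in zip(h.vertices, h.vertices[1:]):
                if (u, v) not in self.edges:
                    raise GraphValidationError(
                        f"haplotype {h.name!r} steps over missing edge ({u!r},{v!r})"
                    )
                supported.add((u, v))
        unsupported = self.edges - supported
        if unsupported:
            u, v = sorted(unsupported)[0]
            raise GraphValidationError(
                f"unsupported edge ({u!r},{v!r}): no haplotype path traverses it"
            )
        for v in self.labels:
            if not self.haps(v):
                raise GraphValidationError(f"vertex {v!r} is covered by no haplotype path")
        if len({h.index for h in self.haplotypes}) != len(self.haplotypes):
            raise GraphValidationError("duplicate haplotype indices")
        for pos, h in enumerate(self.haplotypes):
            if h.index != pos:
                raise GraphValidationError("haplotype indices must be 0..n-1 in order")


@dataclass(frozen=True)
class InferredPath:
    """Ordered (vertex, haplotype-index) steps; Definition-1 semantics.

    Consecutive steps must be graph edges; if two consecutive steps carry the
    same haplotype index, the vertices must be consecutive on that haplotype
    path (so staying on a haplotype means copying it verbatim).
    """

    steps: tuple[tuple[str, int], ...]

    def __len__(self) -> int:
        return len(self.steps)

    def validate(self, graph: PangenomeGraph) -> None:
        if not self.steps:
            raise GraphValidationError("inferred path has no steps")
        for u, h in self.steps:
            if h not in graph.haps(u):
                raise GraphValidationError(
                    f"step ({u!r},{h}) invalid: haplotype {h} does not cover {u!r}"
                )
        for (u, h1), (v, h2) in zip(self.steps, self.steps[1:]):
            if (u, v) not in graph.edges:
                raise GraphValidationError(f"({u!r},{v!r}) is not an edge")
            if h1 == h2:
                hp = graph.haplotype(h1)
                ok = any(
                    hp.vertices[i] == u and hp.vertices[i + 1] == v
                    for i in range(len(hp) - 1)
                )
                if not ok:
                    raise GraphValidationError(
                        f"steps ({u!r},{h1})->({v!r},{h2}) stay on haplotype {h1} "
                        "but are not consecutive on it"
                    )


@dataclass
class StringSet:
    """The query string set S (k-mers or minimizers), with set semantics.

    Each distinct string contributes at most 1 to the cost.  Multiplicities
    (read support) are recorded for reporting only.  ``canonical`` records the
    strand policy under which the strings were produced: if true, a string
    counts as matched when either it or its reverse complement occurs.
    """

    strings: frozenset[str]
    multiplicity: dict[str, int] = field(default_factory=dict)
    canonical: bool = False

    def __post_init__(self) -> None:
        for r in self.strings:
            if len(r) < 2:
                raise ValueError(f"query string {r!r} shorter than 2 characters")

    def __len__(self) -> int:
        return len(self.strings)

    def min_length(self) -> int:
        if not self.strings:
            raise ValueError("empty string set has no minimum length")
        return min(len(r) for r in self.strings)


# ---------------------------------------------------------------------- #
# core operations

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def spell(path: InferredPath | HaplotypePath, graph: PangenomeGraph) -> str:
    """Concatenate vertex labels along a path (epsilon labels vanish)."""
    if isinstance(path, HaplotypePath):
        vs = path.vertices
    else:
        path.validate(graph)
        vs = tuple(u for u, _ in path.steps)
    return "".join(graph.labels[v] for v in vs)


def recombination_count(path: InferredPath) -> int:
    """gamma(P): number of consecutive step pairs changing haplotype."""
    return sum(
        1 for (_, h1), (_, h2) in zip(path.steps, path.steps[1:]) if h1 != h2
    )


def string_matched(r: str, text: str, canonical: bool = False) -> bool:
    if r in text:
        return True
    return canonical and reverse_complement(r) in text


def cost(
    path: InferredPath,
    string_set: StringSet,
    c: float,
    graph: PangenomeGraph,
) -> float:
    """Problem-1 cost: c * gamma(P) + number of unmatched strings in S."""
    if c < 0:
        raise ValueError("recombination penalty c must be non-negative")
    text = spell(path, graph)
    unmatched = sum(
        1
        for r in string_set.strings
        if not string_matched(r, text, string_set.canonical)
    )
    return c * recombination_count(path) + unmatched
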