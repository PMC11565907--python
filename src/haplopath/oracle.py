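"""Brute-force reference for the path-inference objective.

Exhaustively enumerates inferred paths of a small pangenome graph and
evaluates the cost directly on spelled strings (plain substring tests).  This
is an independent code path from the flow/IP stack: it never builds the
expanded graph, never computes hits, and shares only the basic data model.
Used as ground truth in tests; makes no attempt to scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .graph_model import (
    InferredPath,
    PangenomeGraph,
    StringSet,
    string_matched,
)


class EnumerationGuardError(RuntimeError):
    """Raised when path enumeration exceeds the configured cap."""


@dataclass
class OracleResult:
    min_cost: float
    witness: InferredPath
    n_optimal: int
    n_enumerated: int
    witness_recombinations: int


def enumerate_inferred_paths(
    graph: PangenomeGraph,
    max_paths: int = 1_000_000,
    full_span: bool = True,
) -> Iterator[InferredPath]:
    """Yield maximal inferred paths in deterministic order.

    With ``full_span=True`` (the flow-model semantics) a path must start at
    the first vertex of its starting haplotype and end at the last vertex of
    its final haplotype — mirroring the source/sink wiring of the expanded
    graph.  Otherwise paths start at any (vertex, haplotype) step and extend
    forward until no extension exists.
    """
    positions: dict[tuple[str, int], list[int]] = {}
    for h in graph.haplotypes:
        for i, v in enumerate(h.vertices):
            positions.setdefault((v, h.index), []).append(i)

    def extensions(u: str, h: int) -> list[tuple[str, int]]:
        out = []
        hp = graph.haplotype(h)
        for v in graph.out_neighbors(u):
            for h2 in sorted(graph.haps(v)):
                if h2 == h:
                    ok = any(
                        hp.vertices[i + 1] == v
                        for i in positions.get((u, h), [])
                        if i + 1 < len(hp)
                    )
                    if not ok:
                        continue
                out.append((v, h2))
        return out

    if full_span:
        starts = sorted(
            {(h.vertices[0], h.index) for h in graph.haplotypes}
        )
    else:
        starts = sorted(
            (v, j) for v in graph.labels for j in graph.haps(v)
        )

    count = 0
    stack: list[tuple[tuple[tuple[str, int], ...], list[tuple[str, int]]]] = []
    for start in reversed(starts):
        stack.append(((start,), extensions(*start)))
    while stack:
        steps, exts = stack.pop()
        u, h = steps[-1]
        if full_span:
            hp = graph.haplotype(h)
            terminal = u == hp.vertices[-1]
        else:
            terminal = not exts
        if terminal:
            count += 1
            if count > max_paths:
                raise EnumerationGuardError(
                    f"more than {max_paths} inferred paths enumerated"
                )
            yield InferredPath(steps=steps)
        for nxt in reversed(exts):
            stack.append((steps + (nxt,), extensions(*nxt)))


def brute_force_optimum(
    graph: PangenomeGraph,
    string_set: StringSet,
    c: float,
    max_paths: int = 1_000_000,
    full_span: bool = True,
) -> OracleResult:
    """Exact minimum of the path-inference cost by exhaustive enumeration.

    The cost of an inferred path splits into a term that depends only on its
    vertex sequence (the number of unmatched strings against the spelled
    text) and a term that depends on the haplotype annotation (``c`` times
    the recombination count).  Enumerating haplotype annotations explicitly
    is exponential in the number of vertices shared by several haplotypes, so
    instead the DFS enumerates vertex sequences and a per-path dynamic
    program minimises recombinations over all valid annotations — the result
    is identical to scoring every inferred path individually.

    Among equal-cost optima the witness with the fewest recombinations is
    kept (first in enumeration order on further ties), which makes the
    reported recombination count well defined for monotonicity checks.
    """
    positions: dict[tuple[str, int], list[int]] = {}
    for h in graph.haplotypes:
        for i, v in enumerate(h.vertices):
            positions.setdefault((v, h.index), []).append(i)

    def consecutive(u: str, v: str, h: int) -> bool:
        hp = graph.haplotype(h)
        return any(
            hp.vertices[i + 1] == v
            for i in positions.get((u, h), [])
            if i + 1 < len(hp)
        )

    if full_span:
        starts = sorted({h.vertices[0] for h in graph.haplotypes})
    else:
        starts = sorted(graph.labels)

    best: tuple[float, int] | None = None
    witness: InferredPath | None = None
    n_opt = 0
    n_enum = 0

    def evaluate(vertices: tuple[str, ...],
                 state: dict[int, tuple[int, int | None]]) -> None:
        nonlocal best, witness, n_opt, n_enum
        if full_span:
            ends = {h for h in state
                    if graph.haplotype(h).vertices[-1] == vertices[-1]}
        else:
            ends = set(state)
        if not ends:
            return
        n_enum += 1
        if n_enum > max_paths:
            raise EnumerationGuardError(
                f"more than {max_paths} vertex paths evaluated"
            )
        text = "".join(graph.labels[v] for v in vertices)
        unmatched = sum(
            1
            for r in string_set.strings
            if not string_matched(r, text, string_set.canonical)
        )
        gamma = min(state[h][0] for h in ends)
        costv = c * gamma + unmatched
        better = best is None or costv < best[0] - 1e-12
        tied = best is not None and abs(costv - best[0]) <= 1e-12
        if tied:
            n_opt += 1
        if better or (tied and gamma < best[1]):
            if better:
                n_opt = 1
            # rebuild the annotation by following backpointers
            h = min(h for h in ends if state[h][0] == gamma)
            haps_rev = [h]
            for st in reversed(trail):
                prev = st[haps_rev[-1]][1]
                if prev is None:
                    break
                haps_rev.append(prev)
            steps = tuple(zip(vertices, reversed(haps_rev)))
            best = (costv, gamma)
            witness = InferredPath(steps=steps)

    # DFS over vertex sequences; ``trail`` holds the DP state at each
    # position of the current path so witnesses can be reconstructed.
    trail: list[dict[int, tuple[int, int | None]]] = []
    for v0 in starts:
        if full_span:
            init = {
                h.index: (0, None)
                for h in graph.haplotypes
                if h.vertices[0] == v0
            }
        else:
            init = {h: (0, None) for h in sorted(graph.haps(v0))}
        if not init:
            continue
        stack: list[tuple[tuple[str, ...],
                          dict[int, tuple[int, int | None]], bool]] = [
            ((v0,), init, False)
        ]
        while stack:
            vertices, state, expanded = stack.pop()
            if expanded:
                trail.pop()
                continue
            trail.append(state)
            stack.append((vertices, state, True))
            evaluate(vertices, state)
            u = vertices[-1]
            for v in reversed(graph.out_neighbors(u)):
                nxt: dict[int, tuple[int, int | None]] = {}
                for h2 in sorted(graph.haps(v)):
                    cands: list[tuple[int, int]] = []
                    if h2 in state and consecutive(u, v, h2):
                        cands.append((state[h2][0], h2))
                    others = [(state[h][0] + 1, h) for h in state if h != h2]
                    if others:
                        cands.append(min(others))
                    if cands:
                        nxt[h2] = min(cands)
                if nxt:
                    stack.append((vertices + (v,), nxt, False))

    if best is None or witness is None:
        raise ValueError("graph admits no inferred path")
    return OracleResult(
        min_cost=best[0],
        witness=witness,
        n_optimal=n_opt,
        n_enumerated=n_enum,
        witness_recombinations=best[1],
    )
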