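"""Shared fixtures: hand-built toy instances and the solved random suite.

The session-scoped ``suite`` fixture solves 50 seeded random instances once
(five formulation variants each, plus the brute-force oracle) and is shared
by the unit tests and by several acceptance tests, so the expensive solves
run a single time per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest

import haplopath as hp
from haplopath.graph_model import HaplotypePath, PangenomeGraph
from haplopath.ip_solver import FlowSolution
from haplopath.oracle import OracleResult
from haplopath.synthetic import SmallInstance, random_small_instance

SUITE_SEEDS = tuple(range(50))
C_GRID = (0, 1, 2, 5, 100)


def toy_graph() -> PangenomeGraph:
    """Two haplotypes through one SNP bubble: AC-(G|T)-CA."""
    labels = {"f0": "AC", "a0": "G", "a1": "T", "f1": "CA"}
    edges = {("f0", "a0"), ("f0", "a1"), ("a0", "f1"), ("a1", "f1")}
    haplotypes = [
        HaplotypePath(index=0, vertices=("f0", "a0", "f1"), name="h0"),
        HaplotypePath(index=1, vertices=("f0", "a1", "f1"), name="h1"),
    ]
    g = PangenomeGraph(labels=labels, edges=edges, haplotypes=haplotypes)
    g.validate()
    return g


@pytest.fixture
def toy() -> PangenomeGraph:
    return toy_graph()


def two_bubble_graph() -> PangenomeGraph:
    """Two haplotypes through two SNP bubbles: h0=AGCGACAG, h1=AGTGATAG."""
    labels = {"F0": "AG", "x0": "C", "x1": "T", "F1": "GA",
              "y0": "C", "y1": "T", "F2": "AG"}
    paths = [("F0", "x0", "F1", "y0", "F2"), ("F0", "x1", "F1", "y1", "F2")]
    g = PangenomeGraph(
        labels=labels,
        edges={e for p in paths for e in zip(p, p[1:])},
        haplotypes=[HaplotypePath(index=i, vertices=p, name=f"h{i}")
                    for i, p in enumerate(paths)],
    )
    g.validate()
    return g


def three_by_two_graph() -> PangenomeGraph:
    """Three source x two target haplotypes at one recombination site.

    Five haplotypes share a middle flank; three distinct alleles enter it
    and two distinct alleles leave it, so the optimized expanded graph
    (3 + 2 recombination arcs through one intermediate vertex) is strictly
    smaller than the naive all-pairs construction (3 * 2 direct arcs).
    """
    labels = {
        "f0": "AA",
        "p0": "GG", "p1": "CC", "p2": "TT",
        "m": "ACGT",
        "q0": "GT", "q1": "CA",
        "f1": "AA",
    }
    paths = [
        ("f0", "p0", "m", "q0", "f1"),
        ("f0", "p1", "m", "q0", "f1"),
        ("f0", "p2", "m", "q1", "f1"),
        ("f0", "p0", "m", "q1", "f1"),
        ("f0", "p1", "m", "q1", "f1"),
    ]
    edges = {e for p in paths for e in zip(p, p[1:])}
    haplotypes = [
        HaplotypePath(index=i, vertices=p, name=f"h{i}")
        for i, p in enumerate(paths)
    ]
    g = PangenomeGraph(labels=labels, edges=edges, haplotypes=haplotypes)
    g.validate()
    return g


@dataclass
class SolvedInstance:
    """One random instance with all formulation variants solved."""

    seed: int
    inst: SmallInstance
    pre: PangenomeGraph           # preprocessed (label-split + edge-split)
    eg_opt: "hp.ExpandedGraph"
    eg_naive: "hp.ExpandedGraph"
    solutions: dict[str, FlowSolution] = field(default_factory=dict)
    paths: dict[str, "hp.InferredPath"] = field(default_factory=dict)
    oracle: OracleResult | None = None
    oracle_by_c: dict[float, OracleResult] = field(default_factory=dict)


def solve_instance(seed: int, with_oracle_grid: bool = True) -> SolvedInstance:
    inst = random_small_instance(seed)
    S = inst.string_set
    pre = hp.preprocess(inst.graph, min_query_length=S.min_length())
    eg_opt = hp.build_optimized(pre, inst.c)
    eg_naive = hp.build_naive(pre, inst.c)
    hits_opt = hp.find_graph_hits(S, eg_opt)
    hits_naive = hp.find_graph_hits(S, eg_naive)

    rec = SolvedInstance(seed=seed, inst=inst, pre=pre,
                         eg_opt=eg_opt, eg_naive=eg_naive)
    builders = {
        "ilp": (hp.build_ilp, eg_opt, hits_opt, False),
        "iqp": (hp.build_iqp, eg_opt, hits_opt, False),
        "ilp_relaxed": (hp.build_ilp, eg_opt, hits_opt, True),
        "iqp_relaxed": (hp.build_iqp, eg_opt, hits_opt, True),
        "ilp_naive": (hp.build_ilp, eg_naive, hits_naive, False),
    }
    for name, (build, eg, hits, relaxed) in builders.items():
        model = build(eg, hits, inst.c)
        if relaxed:
            model = hp.relax_edge_variables(model)
        sol = hp.solve(model)
        assert sol.status == "optimal", (seed, name, sol.status)
        if relaxed:
            sol = hp.integralize(sol, eg)
        rec.solutions[name] = sol
        rec.paths[name] = hp.extract_inferred_path(sol, eg, pre)

    rec.oracle = hp.brute_force_optimum(pre, S, inst.c)
    if with_oracle_grid:
        for c in C_GRID:
            rec.oracle_by_c[c] = hp.brute_force_optimum(pre, S, c)
    return rec


@pytest.fixture(scope="session")
def suite() -> list[SolvedInstance]:
    return [solve_instance(seed) for seed in SUITE_SEEDS]
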