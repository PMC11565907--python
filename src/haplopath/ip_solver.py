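"""Integer-programming formulations over the expanded graph.

The optimal inferred path is recovered from a unit s→t flow in the expanded
graph GE.  Binary variables x_uv select edges; z_r indicates that query
string r is matched by the selected path; z_rω selects one matching subpath
(hit) per matched string.  The objective

    min  sum weight(u,v) * x_uv  +  sum_r (1 - z_r)

charges the recombination penalty through edge weights and one unit per
unmatched query string.  Two formulations are provided: the ILP ties z_rω to
its edges with one linear constraint per hit; the IQP replaces those with one
quadratic constraint per query string.  Edge variables may be relaxed to
[0, 1]; an optimal relaxed solution is converted to an equal-cost 0/1 path by
:func:`integralize`.

The default backend solves models with HiGHS through ``scipy.optimize.milp``.
Quadratic constraints are linearized exactly inside the backend (products of
a binary z with an x in [0, 1] admit an exact McCormick envelope), so the
quadratic formulation is solved to global optimality as well.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .expanded_graph import ExpandedGraph
from .graph_model import InferredPath, PangenomeGraph
from .hits import Hit, HitIndex


class SolverCapabilityError(RuntimeError):
    """Raised when a backend cannot handle the requested model class."""


@dataclass(frozen=True)
class Variable:
    name: str
    lb: float = 0.0
    ub: float = 1.0
    integral: bool = True


@dataclass
class LinConstraint:
    """lb <= sum coeffs[v] * v <= ub."""

    coeffs: dict[str, float]
    lb: float
    ub: float


@dataclass
class QuadConstraint:
    """Quadratic string-hit constraint for one query string r:

    sum_omega (const_omega + sum_{e in omega} x_e) * z_omega  -  z_r  =  0
    """

    z_r: str
    terms: list[tuple[str, float, tuple[str, ...]]]  # (z_omega, const, x vars)


@dataclass
class IPModel:
    variables: dict[str, Variable]
    objective: dict[str, float]
    offset: float
    linear: list[LinConstraint]
    quadratic: list[QuadConstraint]
    formulation: str  # "ilp" | "iqp"
    relaxed: bool
    edge_vars: dict[tuple[str, str], str]
    z_vars: dict[str, str]
    hit_vars: dict[str, list[tuple[str, Hit]]]
    unmatched_fixed: frozenset[str]
    eg: ExpandedGraph = field(repr=False)

    def n_variables(self) -> int:
        return len(self.variables)

    def n_string_hit_constraints(self) -> int:
        if self.formulation == "iqp":
            return len(self.quadratic)
        return sum(
            1
            for c in self.linear
            if any(v.startswith("zh[") for v in c.coeffs)
            and len([v for v in c.coeffs if v.startswith("zh[")]) == 1
        )

    def to_lp_string(self) -> str:
        """A plain LP-format-style dump for debugging (linear part only)."""
        lines = ["\\ objective offset %g" % self.offset, "Minimize", " obj:"]
        terms = " + ".join(f"{c:g} {v}" for v, c in sorted(self.objective.items()))
        lines.append("  " + terms)
        lines.append("Subject To")
        for i, con in enumerate(self.linear):
            expr = " + ".join(f"{c:g} {v}" for v, c in sorted(con.coeffs.items()))
            if con.lb == con.ub:
                lines.append(f" c{i}: {expr} = {con.lb:g}")
            else:
                if con.lb > -np.inf:
                    lines.append(f" c{i}l: {expr} >= {con.lb:g}")
                if con.ub < np.inf:
                    lines.append(f" c{i}u: {expr} <= {con.ub:g}")
        lines.append("End")
        return "\n".join(lines)


@dataclass
class FlowSolution:
    values: dict[str, float]
    objective: float
    status: str  # optimal | infeasible | time_limit | unbounded | other
    gap: float
    model: IPModel = field(repr=False)

    def edge_value(self, u: str, v: str) -> float:
        return self.values.get(self.model.edge_vars[(u, v)], 0.0)

    def z_value(self, r: str) -> float:
        if r in self.model.unmatched_fixed:
            return 0.0
        return self.values.get(self.model.z_vars[r], 0.0)

    def selected_hits(self) -> list[Hit]:
        out = []
        for r, pairs in self.model.hit_vars.items():
            for var, hit in pairs:
                if self.values.get(var, 0.0) > 0.5:
                    out.append(hit)
        return out


# ---------------------------------------------------------------------- #
# model construction


def _xname(u: str, v: str) -> str:
    return f"x[{u}->{v}]"


def _common(eg: ExpandedGraph, hit_index: HitIndex, c: float):
    if c < 0:
        raise ValueError("recombination penalty c must be non-negative")
    variables: dict[str, Variable] = {}
    objective: dict[str, float] = {}
    edge_vars: dict[tuple[str, str], str] = {}
    for (u, v), w in sorted(eg.edges.items()):
        name = _xname(u, v)
        variables[name] = Variable(name)
        edge_vars[(u, v)] = name
        if w:
            objective[name] = float(w)

    linear: list[LinConstraint] = []
    # Flow conservation with +1 imbalance at s and -1 at t.
    for u in sorted(eg.labels):
        coeffs: dict[str, float] = {}
        for v in eg.out_neighbors(u):
            coeffs[edge_vars[(u, v)]] = coeffs.get(edge_vars[(u, v)], 0.0) + 1.0
        for v in eg.in_neighbors(u):
            coeffs[edge_vars[(v, u)]] = coeffs.get(edge_vars[(v, u)], 0.0) - 1.0
        rhs = 1.0 if u == eg.source else (-1.0 if u == eg.sink else 0.0)
        linear.append(LinConstraint(coeffs=coeffs, lb=rhs, ub=rhs))

    z_vars: dict[str, str] = {}
    hit_vars: dict[str, list[tuple[str, Hit]]] = {}
    offset = 0.0
    unmatched: set[str] = set()
    for r in sorted(hit_index.hits):
        hits = hit_index.hits[r]
        offset += 1.0  # the (1 - z_r) term contributes 1 up front
        if not hits:
            unmatched.add(r)  # z_r pinned to 0: penalty stays in the offset
            continue
        zname = f"z[{r}]"
        variables[zname] = Variable(zname)
        objective[zname] = objective.get(zname, 0.0) - 1.0
        z_vars[r] = zname
        pairs = []
        for i, hit in enumerate(hits):
            hname = f"zh[{r}#{i}]"
            variables[hname] = Variable(hname)
            pairs.append((hname, hit))
        hit_vars[r] = pairs
        # r is matched iff exactly one of its hits is charged
        coeffs = {hname: 1.0 for hname, _ in pairs}
        coeffs[zname] = -1.0
        linear.append(LinConstraint(coeffs=coeffs, lb=0.0, ub=0.0))
    return variables, objective, offset, linear, edge_vars, z_vars, hit_vars, unmatched


def build_ilp(eg: ExpandedGraph, hit_index: HitIndex, c: float) -> IPModel:
    """ILP with one linear string-hit constraint per hit:
    sum_{e in omega} x_e >= |omega| * z_romega."""
    (variables, objective, offset, linear, edge_vars, z_vars, hit_vars,
     unmatched) = _common(eg, hit_index, c)
    for r, pairs in hit_vars.items():
        for hname, hit in pairs:
            coeffs: dict[str, float] = {}
            for u, v in hit.edges:
                xv = edge_vars[(u, v)]
                coeffs[xv] = coeffs.get(xv, 0.0) + 1.0
            coeffs[hname] = coeffs.get(hname, 0.0) - float(len(hit.edges))
            linear.append(LinConstraint(coeffs=coeffs, lb=0.0, ub=np.inf))
    return IPModel(
        variables=variables, objective=objective, offset=offset, linear=linear,
        quadratic=[], formulation="ilp", relaxed=False, edge_vars=edge_vars,
        z_vars=z_vars, hit_vars=hit_vars, unmatched_fixed=frozenset(unmatched),
        eg=eg,
    )


def build_iqp(eg: ExpandedGraph, hit_index: HitIndex, c: float) -> IPModel:
    """IQP with exactly one quadratic string-hit constraint per query string:
    sum_omega (1 - |omega| + sum_{e in omega} x_e) * z_romega = z_r."""
    (variables, objective, offset, linear, edge_vars, z_vars, hit_vars,
     unmatched) = _common(eg, hit_index, c)
    quadratic: list[QuadConstraint] = []
    for r, pairs in hit_vars.items():
        terms = []
        for hname, hit in pairs:
            xs = tuple(edge_vars[(u, v)] for u, v in hit.edges)
            terms.append((hname, 1.0 - float(len(hit.edges)), xs))
        quadratic.append(QuadConstraint(z_r=z_vars[r], terms=terms))
    return IPModel(
        variables=variables, objective=objective, offset=offset, linear=linear,
        quadratic=quadratic, formulation="iqp", relaxed=False,
        edge_vars=edge_vars, z_vars=z_vars, hit_vars=hit_vars,
        unmatched_fixed=frozenset(unmatched), eg=eg,
    )


def relax_edge_variables(model: IPModel) -> IPModel:
    """Relax every edge variable x_uv to the continuous interval [0, 1].

    The z variables stay binary.  Idempotent."""
    out = copy.copy(model)
    out.variables = dict(model.variables)
    for name in model.edge_vars.values():
        var = out.variables[name]
        if var.integral:
            out.variables[name] = Variable(name, var.lb, var.ub, integral=False)
    out.relaxed = True
    return out


# ---------------------------------------------------------------------- #
# backends


class HighsBackend:
    """HiGHS via scipy.optimize.milp.

    Quadratic string-hit constraints are linearized exactly: each product
    z_romega * x_uv is replaced by an auxiliary y in [0, 1] with
    y <= z, y <= x, y >= z + x - 1 (exact because z is binary).
    """

    name = "highs"
    supports_quadratic = True

    def solve(self, model: IPModel, threads: int = 1,
              time_limit: float | None = None) -> FlowSolution:
        names = list(model.variables)
        col = {n: i for i, n in enumerate(names)}
        lb = [model.variables[n].lb for n in names]
        ub = [model.variables[n].ub for n in names]
        integral = [1 if model.variables[n].integral else 0 for n in names]

        rows: list[dict[int, float]] = []
        rlb: list[float] = []
        rub: list[float] = []

        def add_row(coeffs: dict[str, float] | dict[int, float],
                    lo: float, hi: float, by_index: bool = False) -> None:
            if by_index:
                rows.append(coeffs)  # type: ignore[arg-type]
            else:
                rows.append({col[v]: c for v, c in coeffs.items()})  # type: ignore[union-attr]
            rlb.append(lo)
            rub.append(hi)

        for con in model.linear:
            add_row(con.coeffs, con.lb, con.ub)

        # exact linearization of quadratic constraints
        for qi, qc in enumerate(model.quadratic):
            eq_row: dict[int, float] = {col[qc.z_r]: -1.0}
            for ti, (zname, const, xs) in enumerate(qc.terms):
                zi = col[zname]
                eq_row[zi] = eq_row.get(zi, 0.0) + const
                for xj, xname in enumerate(xs):
                    yname = f"y[{qi}.{ti}.{xj}]"
                    names.append(yname)
                    col[yname] = len(names) - 1
                    lb.append(0.0)
                    ub.append(1.0)
                    integral.append(0)
                    yi, xi = col[yname], col[xname]
                    add_row({yi: 1.0, zi: -1.0}, -np.inf, 0.0, by_index=True)
                    add_row({yi: 1.0, xi: -1.0}, -np.inf, 0.0, by_index=True)
                    add_row({yi: 1.0, zi: -1.0, xi: -1.0}, -1.0, np.inf, by_index=True)
                    eq_row[yi] = eq_row.get(yi, 0.0) + 1.0
            add_row(eq_row, 0.0, 0.0, by_index=True)

        n = len(names)
        cvec = np.zeros(n)
        for v, coef in model.objective.items():
            cvec[col[v]] = coef

        data, ri, ci = [], [], []
        for i, row in enumerate(rows):
            for j, coef in row.items():
                ri.append(i)
                ci.append(j)
                data.append(coef)
        amat = sp.csr_matrix((data, (ri, ci)), shape=(len(rows), n))

        options: dict[str, object] = {"mip_rel_gap": 0.0}
        if time_limit is not None:
            options["time_limit"] = float(time_limit)
        res = milp(
            c=cvec,
            constraints=LinearConstraint(amat, np.array(rlb), np.array(rub)),
            integrality=np.array(integral),
            bounds=Bounds(np.array(lb, dtype=float), np.array(ub, dtype=float)),
            options=options,
        )
        status = {0: "optimal", 1: "time_limit", 2: "infeasible",
                  3: "unbounded"}.get(res.status, "other")
        values: dict[str, float] = {}
        if res.x is not None:
            for nme, x in zip(names, res.x):
                xv = float(x)
                if abs(xv - round(xv)) < 1e-6:
                    xv = float(round(xv))
                values[nme] = xv
        objective = model.offset + sum(
            coef * values.get(v, 0.0) for v, coef in model.objective.items()
        ) if values else float("nan")
        return FlowSolution(values=values, objective=objective, status=status,
                            gap=0.0 if status == "optimal" else float("nan"),
                            model=model)


_BACKENDS = {"highs": HighsBackend()}


def get_backend(name: str):
    try:
        return _BACKENDS[name]
    except KeyError:
        raise SolverCapabilityError(
            f"unknown solver backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None


def check_capability(backend_name: str, formulation: str) -> None:
    backend = get_backend(backend_name)
    if formulation == "iqp" and not backend.supports_quadratic:
        raise SolverCapabilityError(
            f"backend {backend_name!r} does not support quadratic constraints"
        )


def solve(model: IPModel, backend: str = "highs", threads: int = 1,
          time_limit: float | None = None) -> FlowSolution:
    """Solve a model; status is one of optimal / infeasible / time_limit / other."""
    check_capability(backend, model.formulation)
    return get_backend(backend).solve(model, threads=threads, time_limit=time_limit)


# ---------------------------------------------------------------------- #
# integralization and path extraction

_TOL = 1e-6


def _flow_conserving(sol: FlowSolution, eg: ExpandedGraph, tol: float = 1e-5) -> bool:
    for u in eg.labels:
        net = sum(sol.edge_value(u, v) for v in eg.out_neighbors(u)) - sum(
            sol.edge_value(v, u) for v in eg.in_neighbors(u)
        )
        want = 1.0 if u == eg.source else (-1.0 if u == eg.sink else 0.0)
        if abs(net - want) > tol:
            return False
    return True


def integralize(solution: FlowSolution, eg: ExpandedGraph) -> FlowSolution:
    """Convert an optimal relaxed solution into an equal-cost 0/1 flow.

    In a unit flow on a DAG, every edge carrying flow 1 lies on *every*
    positive-flow s→t path (all other out-edges of its tail and in-edges of
    its head carry zero).  Every edge of every used hit-subpath carries flow
    1, so the minimum-weight s→t path over the positive-flow support keeps
    every used hit selected, and by optimality of the input its weight equals
    the fractional flow's weight.  Deterministic lowest-id tie-breaking.
    """
    if solution.status != "optimal":
        raise ValueError("can only integralize an optimal solution")
    if not _flow_conserving(solution, eg):
        raise ValueError("input solution does not satisfy flow conservation")

    xvals = {e: solution.values.get(var, 0.0)
             for e, var in solution.model.edge_vars.items()}
    if all(abs(x - round(x)) <= _TOL for x in xvals.values()):
        return solution

    support = {e: w for e, w in eg.edges.items() if xvals[e] > _TOL}
    # DAG shortest path over the support, deterministic
    import graphlib

    adj: dict[str, list[str]] = {v: [] for v in eg.labels}
    preds: dict[str, list[str]] = {v: [] for v in eg.labels}
    for (u, v) in sorted(support):
        adj[u].append(v)
        preds[v].append(u)
    order = tuple(
        graphlib.TopologicalSorter({v: set(preds[v]) for v in eg.labels}).static_order()
    )
    INF = float("inf")
    dist: dict[str, float] = {v: INF for v in eg.labels}
    back: dict[str, str | None] = {v: None for v in eg.labels}
    dist[eg.source] = 0.0
    for v in order:
        if dist[v] == INF:
            continue
        for w in adj[v]:
            cand = dist[v] + support[(v, w)]
            if cand < dist[w] - 1e-12 or (
                abs(cand - dist[w]) <= 1e-12 and (back[w] is None or v < back[w])
            ):
                dist[w] = min(cand, dist[w])
                back[w] = v
    if dist[eg.sink] == INF:
        raise ValueError("no positive-flow path from source to sink")

    path = [eg.sink]
    while path[-1] != eg.source:
        path.append(back[path[-1]])  # type: ignore[arg-type]
    path.reverse()
    path_edges = set(zip(path, path[1:]))

    # used hits must remain fully selected on the chosen path
    for hit in solution.selected_hits():
        for e in hit.edges:
            if e not in path_edges:
                raise AssertionError(
                    "integralization dropped a used hit-subpath edge"
                )

    values = dict(solution.values)
    for e, var in solution.model.edge_vars.items():
        values[var] = 1.0 if e in path_edges else 0.0
    objective = solution.model.offset + sum(
        coef * values.get(v, 0.0) for v, coef in solution.model.objective.items()
    )
    if abs(objective - solution.objective) > 1e-5:
        raise AssertionError(
            f"integralization changed the objective: {solution.objective} "
            f"-> {objective}"
        )
    return FlowSolution(values=values, objective=solution.objective,
                        status="optimal", gap=0.0, model=solution.model)


def extract_inferred_path(
    solution: FlowSolution,
    eg: ExpandedGraph,
    graph: PangenomeGraph | None = None,
) -> InferredPath:
    """Walk the x=1 edges from s to t and map chain vertices back to
    (vertex, haplotype) steps.  Source, sink and w_e vertices are dropped;
    epsilon edge-split vertices are kept as steps so that the haplotype
    switch count of the result equals (path weight) / c exactly."""
    if graph is None:
        graph = eg.graph
    if graph is None:
        raise ValueError("no pangenome graph attached to the expanded graph")
    cur = eg.source
    steps: list[tuple[str, int]] = []
    visited = {cur}
    while cur != eg.sink:
        nxts = [v for v in eg.out_neighbors(cur)
                if solution.edge_value(cur, v) > 1 - 1e-4]
        if len(nxts) != 1:
            raise ValueError(
                f"solution is not a single 0/1 path: vertex {cur!r} has "
                f"{len(nxts)} selected out-edges"
            )
        cur = nxts[0]
        if cur in visited:
            raise ValueError("selected edges revisit a vertex")
        visited.add(cur)
        if cur == eg.sink or cur in eg.edge_vertex_origin:
            continue
        v, j, _ = eg.origin[cur]
        steps.append((v, j))
    path = InferredPath(steps=tuple(steps))
    path.validate(graph)
    return path
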