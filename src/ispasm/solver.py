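"""Constrained shortest-path extraction by LP relaxation with ILP fallback.

One isoform is one s→t path of the MSCG.  The path is chosen to
maximize

    sum_{(i,j) in P} -w[i,j]  +  sum_{p in R'} alpha_p * q_p

over binary indicators f(i,j) (vertex/edge membership) and q_p (read
pattern compatibility), subject to unit flow out of the source, flow
conservation through every internal vertex (in-flow = f(i,i) =
out-flow), and the linking rows q_p <= f(i,i) for i in IS_p and
q_p <= 1 - f(i,i) for i in ES_p.  Finding the exact optimum is
NP-hard in general, but the LP relaxation (variables in [0, 1]) is
integral for the overwhelming majority of loci; only when some
variable strays from {0, 1} by more than a small tolerance is the
problem re-solved as an ILP.  Both are handled by HiGHS through
``scipy.optimize.milp``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .mscg import BIG, MSCG
from .pairing import ReadPattern, is_compatible

__all__ = [
    "PathProblem",
    "PathSolution",
    "PathsExhausted",
    "build_program",
    "solve_path",
    "score_path",
    "dag_shortest_path",
]

#: Absolute tolerance for declaring an LP variable integral.
INTEGRALITY_EPS = 1e-6


class PathsExhausted(RuntimeError):
    """Every remaining s→t route needs an inactivated terminal edge.

    Raised when the optimum path uses a BIG-weight edge — with the
    driver's no-good cuts in place this means no admissible path is
    left in the locus, not a weighting bug."""


@dataclass
class PathProblem:
    graph: MSCG
    patterns: list[ReadPattern]
    keys: list[tuple]          # variable order: f-keys then ("q", idx)
    col: dict[tuple, int]
    c: np.ndarray              # maximization objective coefficients
    A: sp.csr_matrix
    lb: np.ndarray
    ub: np.ndarray
    var_ub: np.ndarray = None  # type: ignore[assignment]

    @property
    def n_vars(self) -> int:
        return len(self.keys)

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    def to_lp_text(self) -> str:
        """CPLEX-LP rendering of the program, for debugging by eye."""

        def vname(key) -> str:
            if key[0] == "q":
                return f"q_{key[1]}"
            return f"f_{key[0]}_{key[1]}"

        lines = ["Maximize", " obj: " + " + ".join(
            f"{self.c[j]:.6g} {vname(k)}"
            for j, k in enumerate(self.keys) if self.c[j] != 0
        )]
        lines.append("Subject To")
        coo = self.A.tocoo()
        rows: dict[int, list[str]] = {}
        for r, cidx, v in zip(coo.row, coo.col, coo.data):
            rows.setdefault(r, []).append(f"{v:+.6g} {vname(self.keys[cidx])}")
        for r in range(self.n_rows):
            expr = " ".join(rows.get(r, ["0"]))
            if self.lb[r] == self.ub[r]:
                lines.append(f" c{r}: {expr} = {self.lb[r]:.6g}")
            else:
                if np.isfinite(self.lb[r]):
                    lines.append(f" c{r}lo: {expr} >= {self.lb[r]:.6g}")
                if np.isfinite(self.ub[r]):
                    lines.append(f" c{r}hi: {expr} <= {self.ub[r]:.6g}")
        lines.append("Bounds")
        ub = self.var_ub if self.var_ub is not None else np.ones(self.n_vars)
        for j, k in enumerate(self.keys):
            lines.append(f" 0 <= {vname(k)} <= {ub[j]:.6g}")
        lines.append("Binaries")
        lines.append(" " + " ".join(vname(k) for k in self.keys))
        lines.append("End")
        return "\n".join(lines) + "\n"


@dataclass
class PathSolution:
    path: tuple[int, ...]      # internal vertices in order
    objective: float
    integral: bool
    q: dict[int, int]          # pattern index -> indicator
    solver_used: str           # "LP" | "ILP"


def _f_keys(graph: MSCG) -> list[tuple[int, int]]:
    M = graph.M
    keys = [(i, i) for i in range(1, M + 1)]
    keys += [(0, i) for i in range(1, M + 1)]
    keys += [(i, M + 1) for i in range(1, M + 1)]
    keys += graph.internal_edges()
    return sorted(keys)


def _prune_patterns(
    graph: MSCG, patterns: Sequence[ReadPattern]
) -> list[ReadPattern]:
    """Drop rows the flow structure already decides.

    An isolated vertex (no internal edges) can only appear on the
    singleton path consisting of itself.  A pattern whose inclusion
    set pairs an isolated vertex with anything else is therefore
    unsatisfiable and is dropped; an isolated vertex in an exclusion
    set can never share a path with the inclusion set, so its linking
    row is redundant.  Both transformations leave the optimum of every
    program unchanged while removing the bulk of the rows contributed
    by stray intronic coverage.
    """
    connected = {i for e in graph.w_edge for i in e}
    out: list[ReadPattern] = []
    for p in patterns:
        if len(p.inclusion) > 1 and not (p.inclusion <= connected):
            continue
        pruned_exc = frozenset(i for i in p.exclusion if i in connected)
        if pruned_exc != p.exclusion:
            p = ReadPattern(
                p.inclusion, pruned_exc, p.alpha,
                multiplicity=p.multiplicity, pseudo=p.pseudo,
            )
        out.append(p)
    return out


def build_program(
    graph: MSCG,
    patterns: Sequence[ReadPattern],
    w_vertex: Optional[np.ndarray] = None,
    w_edge: Optional[dict[tuple[int, int], float]] = None,
    banned_pairs: Sequence[tuple[tuple[int, int], tuple[int, int]]] = (),
    banned_paths: Sequence[Sequence[int]] = (),
) -> PathProblem:
    """Assemble the sparse constraint system for one locus.

    ``w_vertex``/``w_edge`` override the graph's stored weights so the
    iterative driver can apply weight decay without mutating the graph.
    ``banned_pairs`` are internal edge pairs that may not be used
    together (f(e1) + f(e2) <= 1), the driver's cut against chimeric
    paths whose joint splicing no fragment witnesses.
    Rows: 1 source constraint, two conservation rows per internal
    vertex, |IS_p| + |ES_p| linking rows per pattern, one row per
    banned pair.
    """
    M = graph.M
    wv = graph.w_vertex if w_vertex is None else w_vertex
    we = graph.w_edge if w_edge is None else w_edge
    if M < 1:
        raise ValueError("graph has no internal vertices")

    patterns = _prune_patterns(graph, patterns)
    fkeys = _f_keys(graph)
    keys: list[tuple] = list(fkeys)
    keys += [("q", p) for p in range(len(patterns))]
    col = {k: idx for idx, k in enumerate(keys)}

    c = np.zeros(len(keys))
    for (i, j) in fkeys:
        if i == j:
            c[col[(i, j)]] = -wv[i - 1]
        elif i == 0:
            c[col[(i, j)]] = -graph.w_source[j - 1]
        elif j == M + 1:
            c[col[(i, j)]] = -graph.w_sink[i - 1]
        else:
            c[col[(i, j)]] = -we[(i, j)]
    for p, pat in enumerate(patterns):
        c[col[("q", p)]] = pat.alpha

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    r = 0

    def add(entries: list[tuple[int, float]], low: float, high: float) -> None:
        nonlocal r
        for cc, v in entries:
            rows.append(r)
            cols.append(cc)
            vals.append(v)
        lb.append(low)
        ub.append(high)
        r += 1

    # exactly one edge out of the source
    add([(col[(0, i)], 1.0) for i in range(1, M + 1)], 1.0, 1.0)

    in_edges: dict[int, list[tuple[int, int]]] = {i: [(0, i)] for i in range(1, M + 1)}
    out_edges: dict[int, list[tuple[int, int]]] = {i: [(i, M + 1)] for i in range(1, M + 1)}
    for (i, j) in graph.internal_edges():
        out_edges[i].append((i, j))
        in_edges[j].append((i, j))

    # in-flow = f(i,i) and f(i,i) = out-flow for every internal vertex
    for i in range(1, M + 1):
        add(
            [(col[e], 1.0) for e in in_edges[i]] + [(col[(i, i)], -1.0)],
            0.0,
            0.0,
        )
        add(
            [(col[(i, i)], 1.0)] + [(col[e], -1.0) for e in out_edges[i]],
            0.0,
            0.0,
        )

    # q_p <= f(i,i) on IS_p;  q_p <= 1 - f(i,i) on ES_p
    for p, pat in enumerate(patterns):
        qc = col[("q", p)]
        for i in sorted(pat.inclusion):
            add([(qc, 1.0), (col[(i, i)], -1.0)], -np.inf, 0.0)
        for i in sorted(pat.exclusion):
            add([(qc, 1.0), (col[(i, i)], 1.0)], -np.inf, 1.0)

    for e1, e2 in banned_pairs:
        add([(col[e1], 1.0), (col[e2], 1.0)], -np.inf, 1.0)

    # no-good cuts: forbid exactly this internal vertex set (supersets
    # and subsets remain feasible)
    for p in banned_paths:
        pset = set(p)
        entries = [(col[(i, i)], 1.0) for i in sorted(pset)]
        entries += [
            (col[(i, i)], -1.0) for i in range(1, M + 1) if i not in pset
        ]
        add(entries, -np.inf, float(len(pset) - 1))

    A = sp.csr_matrix(
        (vals, (rows, cols)), shape=(r, len(keys)), dtype=float
    )
    prob = PathProblem(
        graph=graph,
        patterns=list(patterns),
        keys=keys,
        col=col,
        c=c,
        A=A,
        lb=np.array(lb),
        ub=np.array(ub),
    )
    # inactivated terminal edges are fixed to zero instead of carrying
    # the BIG coefficient into the solver (kinder numerics; exhaustion
    # of admissible paths then surfaces as infeasibility)
    var_ub = np.ones(len(keys))
    for i in range(1, M + 1):
        if graph.w_source[i - 1] >= BIG:
            var_ub[col[(0, i)]] = 0.0
        if graph.w_sink[i - 1] >= BIG:
            var_ub[col[(i, M + 1)]] = 0.0
    prob.var_ub = var_ub
    return prob


def _run(problem: PathProblem, integral: bool, time_limit: float):
    ub = problem.var_ub if problem.var_ub is not None else 1.0
    res = milp(
        c=-problem.c,
        constraints=LinearConstraint(problem.A, problem.lb, problem.ub),
        bounds=Bounds(0.0, ub),
        integrality=np.full(problem.n_vars, 1 if integral else 0),
        options={"time_limit": time_limit},
    )
    return res


def _extract_path(problem: PathProblem, x: np.ndarray) -> tuple[int, ...]:
    graph = problem.graph
    M = graph.M
    out_edges: dict[int, list[int]] = {0: list(range(1, M + 1))}
    for i in range(1, M + 1):
        out_edges[i] = [M + 1]
    for (i, j) in graph.internal_edges():
        out_edges[i].append(j)
    path: list[int] = []
    cur = 0
    seen = 0
    while cur != M + 1:
        nxt = [j for j in sorted(set(out_edges[cur])) if x[problem.col[(cur, j)]] > 0.5]
        if len(nxt) != 1:
            raise RuntimeError(
                "solution flow does not describe a single s-t path"
            )
        w = graph.edge_weight(cur, nxt[0])
        if w >= BIG:
            raise PathsExhausted(
                "optimal path crosses an inactivated terminal edge"
            )
        cur = nxt[0]
        if cur != M + 1:
            path.append(cur)
        seen += 1
        if seen > M + 2:
            raise RuntimeError("cycle detected while reconstructing the path")
    return tuple(path)


def solve_path(
    problem: PathProblem,
    mode: str = "auto",
    time_limit: float = 60.0,
) -> PathSolution:
    """Solve the path program.

    ``auto`` solves the LP first and accepts it when every variable is
    within INTEGRALITY_EPS of {0, 1}; otherwise the ILP is solved.
    The returned objective is recomputed from the reconstructed path
    and asserted equal to the solver's.
    """
    if mode not in {"auto", "lp", "ilp"}:
        raise ValueError(f"unknown mode {mode!r}")
    solver_used = "LP"
    if mode == "ilp":
        res = _run(problem, True, time_limit)
        solver_used = "ILP"
    else:
        res = _run(problem, False, time_limit)
    if not res.success:
        if res.status == 2:  # infeasible: every admissible path cut off
            raise PathsExhausted(res.message)
        raise RuntimeError(f"LP/ILP solve failed: {res.message}")
    x = res.x
    off = np.abs(x - np.round(x)).max() if len(x) else 0.0
    if off > INTEGRALITY_EPS:
        if mode == "lp":
            raise RuntimeError(
                "LP relaxation is fractional; re-run with mode='auto' or 'ilp'"
            )
        res = _run(problem, True, time_limit)
        if not res.success:
            if res.status == 2:
                raise PathsExhausted(res.message)
            if res.status == 1 and res.x is not None:
                # time limit with an incumbent: use the best feasible
                # integral solution found so far
                import warnings

                warnings.warn(
                    "ILP time limit reached; using the incumbent solution"
                )
            else:
                raise RuntimeError(f"ILP fallback failed: {res.message}")
        x = res.x
        solver_used = "ILP"
        off = np.abs(x - np.round(x)).max() if len(x) else 0.0
        if off > 1e-5:
            raise RuntimeError("ILP returned a fractional solution")
    x = np.round(x)
    path = _extract_path(problem, x)
    # q is re-derived from the path: the linking rows make its true
    # value the compatibility indicator, and the MIP backend has been
    # seen leaving a satisfiable q at zero within its feasibility
    # tolerance, undercounting the objective by that pattern's reward
    pset = set(path)
    q = {
        p: int(pat.inclusion <= pset and not (pat.exclusion & pset))
        for p, pat in enumerate(problem.patterns)
    }
    objective = score_path(path, problem.graph, problem.patterns, problem=problem)
    solver_obj = float(problem.c @ x)
    if solver_obj - objective > 1e-6 * max(1.0, abs(solver_obj)):
        raise RuntimeError(
            f"solver over-claims: path score {objective} vs {solver_obj}"
        )
    return PathSolution(
        path=path,
        objective=objective,
        integral=True,
        q=q,
        solver_used=solver_used,
    )


def score_path(
    path: Sequence[int],
    graph: MSCG,
    patterns: Sequence[ReadPattern],
    problem: Optional[PathProblem] = None,
) -> float:
    """Objective of a given s→t path (internal vertices only).

    Sum of negated weights along the path — vertices, internal edges
    and the two terminal edges — plus the rewards of every compatible
    pattern.  When called from the solver, the (possibly decayed)
    weights are read back out of the problem's objective vector.
    """
    path = tuple(path)
    if not path:
        raise ValueError("empty path")

    def w(i: int, j: int) -> float:
        if problem is not None:
            return -problem.c[problem.col[(i, j)]]
        return graph.vertex_weight(i) if i == j else graph.edge_weight(i, j)

    if problem is None:
        valid = set(graph.internal_edges())
        for i, j in zip(path, path[1:]):
            if (i, j) not in valid:
                raise ValueError(f"edge ({i}, {j}) not in graph")
    total = -w(0, path[0]) - w(path[-1], graph.M + 1)
    for i in path:
        total -= w(i, i)
    for i, j in zip(path, path[1:]):
        total -= w(i, j)
    for pat in patterns:
        if is_compatible(pat, path):
            total += pat.alpha
    return float(total)


def dag_shortest_path(
    graph: MSCG,
    w_vertex: Optional[np.ndarray] = None,
    w_edge: Optional[dict[tuple[int, int], float]] = None,
) -> tuple[tuple[int, ...], float]:
    """Minimum-weight s→t path by dynamic programming in index order.

    With alpha = 0 the full problem reduces to exactly this; the
    driver never calls it, but it is the natural cross-check and is
    exposed for that purpose.
    """
    M = graph.M
    wv = graph.w_vertex if w_vertex is None else w_vertex
    we = graph.w_edge if w_edge is None else w_edge
    dist = {0: 0.0}
    back: dict[int, int] = {}
    in_edges: dict[int, list[int]] = {i: [0] for i in range(1, M + 1)}
    for (i, j) in we:
        in_edges[j].append(i)
    for j in range(1, M + 1):
        best = None
        arg = None
        for i in sorted(set(in_edges[j])):
            if i not in dist:
                continue
            ew = graph.w_source[j - 1] if i == 0 else we[(i, j)]
            cand = dist[i] + ew + wv[j - 1]
            if best is None or cand < best:
                best, arg = cand, i
        if best is not None:
            dist[j] = best
            back[j] = arg
    best = None
    arg = None
    for i in range(1, M + 1):
        if i not in dist:
            continue
        cand = dist[i] + graph.w_sink[i - 1]
        if best is None or cand < best:
            best, arg = cand, i
    if arg is None:
        raise RuntimeError("no s-t path in graph")
    path = [arg]
    while back[path[-1]] != 0:
        path.append(back[path[-1]])
    return tuple(reversed(path)), float(best)
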