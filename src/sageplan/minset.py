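"""Minimum-set reserve selection with boundary penalties.

The core problem: choose a binary selection x over planning units that
minimizes

    sum_i c_i x_i  +  b * [ sum_i p*_i x_i  -  2 * sum_(ij) L_ij y_ij ]

subject to per-feature representation targets sum_i f_ki x_i >= t_k,
locked-in units forced to 1, and linking constraints y_ij <= x_i,
y_ij <= x_j with y in [0, 1] (exact at the optimum for b >= 0).  Here
p*_i = (shared-edge perimeter of unit i) + edge_factor * (study-edge
length of unit i), and L_ij is the shared edge length of an adjacent pair,
so the bracket equals the exposed boundary of the selected set with
study-area edges down-weighted by the edge factor.

Backends: 'milp' (HiGHS via scipy.optimize.milp, solved to a relative
optimality gap), 'exhaustive' (exact enumeration, the test oracle, n <= 22),
and 'greedy' (fast feasible fallback).  Targets are hard constraints in all
backends; the gap applies to the objective only.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import LinearConstraint, milp
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components

from .units import PlanningUnitSet

__all__ = [
    "Target",
    "ProblemSpec",
    "Solution",
    "formulate",
    "solve",
    "boundary_term",
    "capture_report",
    "calibrate_boundary_penalty",
]

DEFAULT_GAP = 0.01
DEFAULT_EDGE_FACTOR = 0.5


@dataclass(frozen=True)
class Target:
    """A per-feature representation target.

    kind 'relative': capture at least ``value`` (in [0, 1]) of the feature's
    total over all units.  kind 'absolute': capture at least ``value`` in
    the feature's own units.
    """

    kind: str
    value: float

    def __post_init__(self):
        if self.kind not in ("relative", "absolute"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.kind == "relative" and not (0.0 <= self.value <= 1.0):
            raise ValueError("relative target must be in [0, 1]")
        if self.value < 0:
            raise ValueError("target value must be >= 0")


@dataclass
class ProblemSpec:
    """A fully specified minimum-set problem over one planning-unit set."""

    units: PlanningUnitSet
    cost: np.ndarray
    features: dict[str, np.ndarray]
    targets: dict[str, Target]
    boundary_penalty: float = 0.0
    edge_factor: float = DEFAULT_EDGE_FACTOR
    locked_in: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    gap: float = DEFAULT_GAP

    def __post_init__(self):
        n = self.units.n_units
        self.cost = np.asarray(self.cost, dtype=np.float64)
        if self.cost.shape != (n,):
            raise ValueError("cost must have one value per unit")
        if not np.all(np.isfinite(self.cost)):
            raise ValueError("cost must be finite")
        for k, f in self.features.items():
            f = np.asarray(f, dtype=np.float64)
            if f.shape != (n,):
                raise ValueError(f"feature {k!r} must have one value per unit")
            if np.any(f < 0):
                raise ValueError(f"feature {k!r} has negative values")
            self.features[k] = f
        for k in self.targets:
            if k not in self.features:
                raise ValueError(f"target set for unknown feature {k!r}")
        if self.boundary_penalty < 0:
            raise ValueError("boundary_penalty must be >= 0")
        if not (0.0 <= self.edge_factor <= 1.0):
            raise ValueError("edge_factor must be in [0, 1]")
        self.locked_in = np.asarray(self.locked_in, dtype=np.int64)
        if self.locked_in.size and (self.locked_in.min() < 0 or self.locked_in.max() >= n):
            raise ValueError("locked_in must index into the unit set")

    def absolute_targets(self) -> dict[str, float]:
        """Resolve targets to absolute amounts; zero-total features with a
        positive relative target resolve to 0 (vacuous) with a warning."""
        out = {}
        for k, t in self.targets.items():
            if t.kind == "absolute":
                out[k] = t.value
            else:
                total = float(self.features[k].sum())
                if total == 0 and t.value > 0:
                    warnings.warn(
                        f"feature {k!r} has zero total; relative target {t.value} is vacuous")
                out[k] = t.value * total
        return out


@dataclass
class Solution:
    """A solved selection with its accounting."""

    selected: np.ndarray              # bool per unit
    objective: float                  # cost + b * boundary
    cost_component: float             # sum of cost over selected
    boundary_component: float         # exposed-boundary value (before b)
    captured: dict[str, tuple[float, float]]  # feature -> (absolute, proportion)
    status: str                       # optimal | within_gap | infeasible
    bound: float | None = None        # best proven lower bound
    violated: list[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


def boundary_term(selected: np.ndarray, units: PlanningUnitSet,
                  edge_factor: float = DEFAULT_EDGE_FACTOR) -> float:
    """Exposed boundary of a selected set, study edges at ``edge_factor``.

    Equals sum_i x_i p*_i - 2 sum_(ij) L_ij x_i x_j with
    p*_i = shared-edge perimeter + edge_factor * study-edge length; shared
    edges between two selected units cancel out.
    """
    selected = np.asarray(selected, dtype=bool)
    cs = units.cell_size
    shared_perim = cs * 4.0 - units.study_edge_length  # per unit
    total = float(np.sum(selected * (shared_perim + edge_factor * units.study_edge_length)))
    if units.adjacency.size:
        both = selected[units.adjacency[:, 0]] & selected[units.adjacency[:, 1]]
        total -= 2.0 * cs * float(both.sum())
    return total


def _capture(selected: np.ndarray, features: dict[str, np.ndarray]) -> dict[str, tuple[float, float]]:
    out = {}
    for k, f in features.items():
        total = float(f.sum())
        got = float(f[selected].sum())
        out[k] = (got, got / total if total > 0 else 0.0)
    return out


def capture_report(solution: Solution, features: dict[str, np.ndarray]) -> dict[str, float]:
    """Proportion of each feature's total captured by the solution
    (targeted or not) — the cross-capture ingredient for umbrella-species
    matrices."""
    return {k: v[1] for k, v in _capture(solution.selected, features).items()}


@dataclass
class Formulation:
    """The abstract integer program: minimize c_x . x + c_y . y subject to
    A [x; y] <= / >= bounds, x binary, y in [0, 1]."""

    n_units: int
    n_pairs: int
    obj: np.ndarray
    constraints: list[LinearConstraint]
    integrality: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    abs_targets: dict[str, float]


def formulate(spec: ProblemSpec) -> Formulation:
    """Build the mixed-integer program for a problem spec.

    With boundary_penalty 0 no y variables are created and the objective is
    plain sum c_i x_i.
    """
    n = spec.units.n_units
    b = spec.boundary_penalty
    cs = spec.units.cell_size
    use_y = b > 0 and spec.units.adjacency.size > 0
    pairs = spec.units.adjacency if use_y else np.empty((0, 2), dtype=np.int64)
    npairs = pairs.shape[0]

    obj = np.zeros(n + npairs)
    obj[:n] = spec.cost
    if b > 0:
        shared_perim = cs * 4.0 - spec.units.study_edge_length
        obj[:n] += b * (shared_perim + spec.edge_factor * spec.units.study_edge_length)
        obj[n:] = -2.0 * b * cs

    constraints: list[LinearConstraint] = []
    abs_targets = spec.absolute_targets()
    if abs_targets:
        rows, cols, vals, lbs = [], [], [], []
        for r, (k, t) in enumerate(abs_targets.items()):
            f = spec.features[k]
            nz = np.flatnonzero(f)
            rows.extend([r] * nz.size)
            cols.extend(nz.tolist())
            vals.extend(f[nz].tolist())
            lbs.append(t)
        A = coo_matrix((vals, (rows, cols)), shape=(len(abs_targets), n + npairs)).tocsr()
        constraints.append(LinearConstraint(A, lb=np.array(lbs), ub=np.inf))
    if npairs:
        # y_p <= x_i and y_p <= x_j
        m = npairs
        rows = np.concatenate([np.arange(m), np.arange(m), np.arange(m, 2 * m), np.arange(m, 2 * m)])
        cols = np.concatenate([n + np.arange(m), pairs[:, 0], n + np.arange(m), pairs[:, 1]])
        vals = np.concatenate([np.ones(m), -np.ones(m), np.ones(m), -np.ones(m)])
        A = coo_matrix((vals, (rows, cols)), shape=(2 * m, n + npairs)).tocsr()
        constraints.append(LinearConstraint(A, lb=-np.inf, ub=0.0))

    lb = np.zeros(n + npairs)
    ub = np.ones(n + npairs)
    lb[spec.locked_in] = 1.0
    integrality = np.zeros(n + npairs)
    integrality[:n] = 1
    return Formulation(n_units=n, n_pairs=npairs, obj=obj, constraints=constraints,
                       integrality=integrality, lb=lb, ub=ub, abs_targets=abs_targets)


def _finish(spec: ProblemSpec, selected: np.ndarray, status: str,
            bound: float | None = None, violated: list[str] | None = None) -> Solution:
    cost_c = float(spec.cost[selected].sum())
    bterm = boundary_term(selected, spec.units, spec.edge_factor)
    return Solution(
        selected=selected,
        objective=cost_c + spec.boundary_penalty * bterm,
        cost_component=cost_c,
        boundary_component=bterm,
        captured=_capture(selected, spec.features),
        status=status,
        bound=bound,
        violated=violated or [],
    )


def _infeasible(spec: ProblemSpec, violated: list[str]) -> Solution:
    n = spec.units.n_units
    return Solution(
        selected=np.zeros(n, dtype=bool), objective=np.inf, cost_component=np.inf,
        boundary_component=0.0, captured=_capture(np.zeros(n, dtype=bool), spec.features),
        status="infeasible", bound=None, violated=violated)


def _impossible_targets(spec: ProblemSpec, abs_targets: dict[str, float]) -> list[str]:
    """Features whose target exceeds what the whole pool can provide."""
    bad = []
    for k, t in abs_targets.items():
        if spec.features[k].sum() < t - 1e-9 * max(1.0, t):
            bad.append(k)
    return bad


def solve(spec: ProblemSpec, backend: str = "milp") -> Solution:
    """Solve a minimum-set problem.

    backend 'milp' returns status 'within_gap' at relative gap <= spec.gap;
    'exhaustive' returns the true optimum (deterministic tie-breaking:
    lexicographically smallest selection among equal objectives; n <= 22);
    'greedy' returns a feasible solution or infeasible.  All backends agree
    on feasibility; an infeasible problem names the violated features.
    """
    if backend == "milp":
        return _solve_milp(spec)
    if backend == "exhaustive":
        return _solve_exhaustive(spec)
    if backend == "greedy":
        return _solve_greedy(spec)
    raise ValueError(f"unknown backend {backend!r}")


def _solve_milp(spec: ProblemSpec) -> Solution:
    n = spec.units.n_units
    if n == 0:
        return _infeasible(spec, sorted(spec.targets))
    form = formulate(spec)
    bad = _impossible_targets(spec, form.abs_targets)
    if bad:
        return _infeasible(spec, bad)
    from scipy.optimize import Bounds
    res = milp(
        c=form.obj,
        constraints=form.constraints,
        integrality=form.integrality,
        bounds=Bounds(form.lb, form.ub),
        options={"mip_rel_gap": spec.gap, "presolve": True},
    )
    if res.status == 2 or res.x is None:  # infeasible
        return _infeasible(spec, bad or sorted(form.abs_targets))
    selected = res.x[:n] > 0.5
    bound = float(res.mip_dual_bound) if getattr(res, "mip_dual_bound", None) is not None else None
    sol = _finish(spec, selected, "within_gap", bound=bound)
    return sol


def _lex_key(selected: np.ndarray) -> tuple:
    return tuple(np.flatnonzero(selected))


def _solve_exhaustive(spec: ProblemSpec) -> Solution:
    n = spec.units.n_units
    if n == 0:
        return _infeasible(spec, sorted(spec.targets))
    if n > 22:
        raise ValueError("exhaustive backend limited to 22 units")
    abs_targets = spec.absolute_targets()
    locked = np.zeros(n, dtype=bool)
    locked[spec.locked_in] = True
    free = np.flatnonzero(~locked)
    fmat = {k: spec.features[k] for k in abs_targets}
    best_obj = np.inf
    best_sel = None
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            sel = locked.copy()
            sel[list(combo)] = True
            ok = all(fmat[k][sel].sum() >= t - 1e-12 for k, t in abs_targets.items())
            if not ok:
                continue
            obj = float(spec.cost[sel].sum()) + spec.boundary_penalty * boundary_term(
                sel, spec.units, spec.edge_factor)
            if obj < best_obj - 1e-12 or (
                abs(obj - best_obj) <= 1e-12 and best_sel is not None
                and _lex_key(sel) < _lex_key(best_sel)
            ):
                best_obj, best_sel = obj, sel
    if best_sel is None:
        return _infeasible(spec, _impossible_targets(spec, abs_targets) or sorted(abs_targets))
    return _finish(spec, best_sel, "optimal", bound=best_obj)


def _solve_greedy(spec: ProblemSpec) -> Solution:
    """Weighted set-cover greedy: repeatedly add the unit with the best
    target-progress per unit cost until all targets are met."""
    n = spec.units.n_units
    if n == 0:
        return _infeasible(spec, sorted(spec.targets))
    abs_targets = spec.absolute_targets()
    bad = _impossible_targets(spec, abs_targets)
    if bad:
        return _infeasible(spec, bad)
    sel = np.zeros(n, dtype=bool)
    sel[spec.locked_in] = True
    remaining = {k: t - float(spec.features[k][sel].sum()) for k, t in abs_targets.items()}
    eps = 1e-12
    cost_floor = max(np.abs(spec.cost).max(), 1.0) * 1e-9
    while any(v > eps for v in remaining.values()):
        gain = np.zeros(n)
        for k, rem in remaining.items():
            if rem > eps:
                gain += np.minimum(spec.features[k], rem) / max(rem, eps)
        gain[sel] = 0.0
        if gain.max() <= eps:
            return _infeasible(spec, [k for k, v in remaining.items() if v > eps])
        score = gain / np.maximum(spec.cost, cost_floor)
        i = int(np.argmax(score))
        sel[i] = True
        for k in remaining:
            remaining[k] = max(0.0, remaining[k] - float(spec.features[k][i]))
    return _finish(spec, sel, "within_gap")


def _clump_count(selected: np.ndarray, units: PlanningUnitSet) -> int:
    idx = np.flatnonzero(selected)
    if idx.size == 0:
        return 0
    pos = np.full(units.n_units, -1, dtype=np.int64)
    pos[idx] = np.arange(idx.size)
    adj = units.adjacency
    if adj.size:
        both = selected[adj[:, 0]] & selected[adj[:, 1]]
        sub = adj[both]
        g = coo_matrix((np.ones(sub.shape[0]), (pos[sub[:, 0]], pos[sub[:, 1]])),
                       shape=(idx.size, idx.size))
    else:
        g = coo_matrix((idx.size, idx.size))
    ncomp, _ = connected_components(g, directed=False)
    return int(ncomp)


def calibrate_boundary_penalty(
    spec: ProblemSpec,
    candidates: list[float],
    inflation_tolerance: float,
    backend: str = "milp",
) -> tuple[float, pd.DataFrame]:
    """Sweep boundary-penalty candidates and pick the strongest affordable one.

    Solves the b = 0 problem, then each candidate; returns the largest b
    whose pure-cost component inflates over the b = 0 optimum by at most
    ``inflation_tolerance`` (relative), together with a per-candidate report
    (cost inflation, clump count, exposed boundary).  If no candidate
    qualifies, returns 0 with a warning.
    """
    if sorted(candidates) != list(candidates):
        raise ValueError("candidates must be sorted ascending")
    base_spec = ProblemSpec(
        units=spec.units, cost=spec.cost, features=dict(spec.features),
        targets=dict(spec.targets), boundary_penalty=0.0,
        edge_factor=spec.edge_factor, locked_in=spec.locked_in, gap=spec.gap)
    base = solve(base_spec, backend)
    if base.status == "infeasible":
        raise ValueError("b = 0 problem must be feasible for calibration")
    rows = []
    chosen = 0.0
    for b in candidates:
        s = ProblemSpec(units=spec.units, cost=spec.cost, features=dict(spec.features),
                        targets=dict(spec.targets), boundary_penalty=b,
                        edge_factor=spec.edge_factor, locked_in=spec.locked_in, gap=spec.gap)
        sol = solve(s, backend)
        if sol.status == "infeasible":
            inflation = np.inf
        else:
            denom = base.cost_component if base.cost_component > 0 else 1.0
            inflation = (sol.cost_component - base.cost_component) / denom
        rows.append({
            "b": b,
            "status": sol.status,
            "cost_component": sol.cost_component,
            "cost_inflation": inflation,
            "n_selected": sol.n_selected,
            "n_clumps": _clump_count(sol.selected, spec.units) if sol.status != "infeasible" else 0,
            "exposed_boundary": sol.boundary_component,
        })
        if np.isfinite(inflation) and inflation <= inflation_tolerance:
            chosen = max(chosen, b)
    report = pd.DataFrame(rows)
    if chosen == 0.0 and (not candidates or candidates[-1] != 0.0):
        if not any(r["cost_inflation"] <= inflation_tolerance and r["b"] > 0 for r in rows):
            warnings.warn("no boundary-penalty candidate met the inflation tolerance; using 0")
    return chosen, report
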