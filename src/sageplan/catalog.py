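"""The problem catalog, uncertainty sweep, and reporting.

Nine problem configurations cover three planning goals:

* set 1 — protect intact sagebrush habitat (1a uniform cost; 1b sagebrush
  connectivity as cost; 1c projected future cover as cost; 1d spring soil
  moisture as cost with optional future-cover masks);
* set 2 — restore degraded sagebrush (2a resilience-driven restoration with
  intact habitat locked in; 2b the same problem swept over uncertainty
  penalty weights);
* set 3 — work within an existing conservation design's core and
  growth-opportunity areas (3a connectivity-focused protection; 3b
  resilience-focused restoration locked to 3a's sites; 3c restoration of
  lost connectivity locked to 3a's sites).

Every problem is a minimum-set selection with relative species targets of
0.2, binary decisions and a 0.01 optimality gap; boundary penalties (edge
factor 0.5) follow the per-problem defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import cached_property

import numpy as np
import pandas as pd
import shapely

from . import connectivity as conn
from .geodata import PolygonLayer, RasterGrid, rescale01
from .minset import ProblemSpec, Solution, Target, capture_report, solve
from .synth import LandscapeBundle
from .units import (
    PlanningUnitSet,
    build_units,
    classify_degraded,
    classify_intact,
    ecological_potential,
    mask_by_future_cover,
    shift_positive,
    subset_units,
    transpose_max,
    utility_cost,
    utility_feature,
)

__all__ = [
    "ProblemCatalogEntry",
    "default_catalog",
    "PreparedLandscape",
    "RunResult",
    "run_catalog_problem",
    "SensitivityMap",
    "SweepResult",
    "uncertainty_sweep",
    "DEFAULT_SWEEP_WEIGHTS",
    "summarize_solution",
    "umbrella_matrix",
    "overlap_report",
    "scd_chain",
]

RELATIVE_TARGET = 0.2
NOMINAL_PENALTY = 1e-5
DEFAULT_SWEEP_WEIGHTS = tuple(np.round(np.arange(0.0, 0.81, 0.1), 10))

COST_RECIPES = (
    "uniform",
    "transposed_sagebrush_connectivity",
    "transposed_future_cover",
    "soil_moisture",
    "transposed_soil_moisture",
    "transposed_lek_connectivity",
    "shifted_connectivity_loss",
)


@dataclass(frozen=True)
class ProblemCatalogEntry:
    """One row of the problem catalog (defaults mirror the shipped config)."""

    id: str
    description: str
    planning_unit_source: str          # intact | degraded | merged
    cost_recipe: str
    feature_recipe: str                # direct | ecological_potential
    locked_in_recipe: str = "none"     # none | intact | prior_solution
    boundary_penalty: float = 0.0
    edge_factor: float = 0.5
    gap: float = 0.01
    future_cover_threshold: float | None = None
    conservation_area_mask: bool = False
    target_species: str | None = None  # None = all species at the target
    relative_target: float = RELATIVE_TARGET
    include_lek_abundance: bool = False
    require_cv: bool = False           # drop features without CV (sweep)

    def __post_init__(self):
        if self.planning_unit_source not in ("intact", "degraded", "merged"):
            raise ValueError(f"unknown planning_unit_source {self.planning_unit_source!r}")
        if self.cost_recipe not in COST_RECIPES:
            raise ValueError(f"unknown cost_recipe {self.cost_recipe!r}")
        if self.feature_recipe not in ("direct", "ecological_potential"):
            raise ValueError(f"unknown feature_recipe {self.feature_recipe!r}")
        if self.locked_in_recipe not in ("none", "intact", "prior_solution"):
            raise ValueError(f"unknown locked_in_recipe {self.locked_in_recipe!r}")


def default_catalog() -> dict[str, ProblemCatalogEntry]:
    """The nine stock problem configurations (1a-1d, 2a-2b, 3a-3c)."""
    return {
        "1a": ProblemCatalogEntry(
            id="1a", description="protect habitat, uniform cost",
            planning_unit_source="intact", cost_recipe="uniform",
            feature_recipe="direct", boundary_penalty=NOMINAL_PENALTY),
        "1b": ProblemCatalogEntry(
            id="1b", description="protect habitat with high sagebrush connectivity",
            planning_unit_source="intact", cost_recipe="transposed_sagebrush_connectivity",
            feature_recipe="direct"),
        "1c": ProblemCatalogEntry(
            id="1c", description="protect habitat with high projected future cover",
            planning_unit_source="intact", cost_recipe="transposed_future_cover",
            feature_recipe="direct"),
        "1d": ProblemCatalogEntry(
            id="1d", description="protect low-resilience habitat (low soil moisture)",
            planning_unit_source="intact", cost_recipe="soil_moisture",
            feature_recipe="direct", boundary_penalty=NOMINAL_PENALTY),
        "2a": ProblemCatalogEntry(
            id="2a", description="restore where restoration is most feasible",
            planning_unit_source="merged", cost_recipe="transposed_soil_moisture",
            feature_recipe="ecological_potential", locked_in_recipe="intact",
            boundary_penalty=0.1, include_lek_abundance=True),
        "2b": ProblemCatalogEntry(
            id="2b", description="restoration under input-data uncertainty",
            planning_unit_source="degraded", cost_recipe="transposed_soil_moisture",
            feature_recipe="ecological_potential", include_lek_abundance=True,
            require_cv=True),
        "3a": ProblemCatalogEntry(
            id="3a", description="connectivity-focused protection in conservation areas",
            planning_unit_source="intact", cost_recipe="transposed_lek_connectivity",
            feature_recipe="direct", conservation_area_mask=True),
        "3b": ProblemCatalogEntry(
            id="3b", description="resilience-focused restoration in conservation areas",
            planning_unit_source="degraded", cost_recipe="transposed_soil_moisture",
            feature_recipe="ecological_potential", locked_in_recipe="prior_solution",
            conservation_area_mask=True, boundary_penalty=2.5,
            include_lek_abundance=True),
        "3c": ProblemCatalogEntry(
            id="3c", description="restore lost connectivity in conservation areas",
            planning_unit_source="degraded", cost_recipe="shifted_connectivity_loss",
            feature_recipe="ecological_potential", locked_in_recipe="prior_solution",
            conservation_area_mask=True, boundary_penalty=1.5,
            include_lek_abundance=True),
    }


#: calibrated single-species boundary penalty for restoration (within the
#: 0.006-0.024 band used for individual species)
SINGLE_SPECIES_RESTORATION_PENALTY = 0.015


def single_species_entry(entry: ProblemCatalogEntry, species: str) -> ProblemCatalogEntry:
    """Variant with one species targeted at the relative target and all other
    species' targets set to 0.  The nominal anti-fragmentation penalty is an
    all-species device, so single-species protection runs drop it."""
    b = entry.boundary_penalty
    if entry.id.startswith("1"):
        b = 0.0
    elif entry.id == "2a":
        b = SINGLE_SPECIES_RESTORATION_PENALTY
    return replace(entry, id=f"{entry.id}:{species}", target_species=species,
                   boundary_penalty=b)


class PreparedLandscape:
    """Derived products of a landscape bundle, computed once and cached.

    Holds the degraded/intact classification, planning-unit sets, rescaled
    feature layers, ecological-potential imputations, and the connectivity
    surfaces.  ``window`` controls the connectivity moving window; the
    default is a desk-scale window (600 m radius, stride 4) matched to the
    bundled 100x100-cell landscapes.
    """

    def __init__(self, bundle: LandscapeBundle, window: conn.WindowConfig | None = None):
        self.bundle = bundle
        self.window = window or conn.WindowConfig(radius=600.0, stride=4)

    # -- classification -----------------------------------------------------
    @cached_property
    def degraded(self) -> np.ndarray:
        return classify_degraded(self.bundle.historic_cover,
                                 self.bundle.potential_cover,
                                 self.bundle.current_cover)

    @cached_property
    def intact(self) -> np.ndarray:
        return classify_intact(self.bundle.current_cover, self.degraded)

    @cached_property
    def conservation_mask(self) -> np.ndarray:
        from .geodata import polygon_membership
        members = polygon_membership(self.bundle.conservation_areas,
                                     self.bundle.current_cover)
        out = np.zeros(self.bundle.current_cover.shape, dtype=bool)
        for m in members.values():
            out |= m
        return out

    # -- features -----------------------------------------------------------
    @cached_property
    def rescaled_features(self) -> dict[str, RasterGrid]:
        """All feature layers rescaled to [0, 1] (aids optimization and puts
        densities and probabilities on one scale)."""
        out = {k: rescale01(g) for k, g in self.bundle.features.items()}
        out["lek_abundance"] = rescale01(self.bundle.lek_abundance)
        return out

    @cached_property
    def potential_features(self) -> dict[str, RasterGrid]:
        """Ecological-potential imputation per species (not lek abundance,
        which is already a cluster-level product)."""
        out = {}
        for k in self.bundle.features:
            out[k] = ecological_potential(
                self.rescaled_features[k], self.intact,
                self.bundle.cluster_zones, self.degraded)
        return out

    @cached_property
    def feature_cv(self) -> dict[str, RasterGrid]:
        out = dict(self.bundle.feature_cv)
        out["lek_abundance"] = self.bundle.lek_abundance_cv
        return out

    # -- connectivity -------------------------------------------------------
    @cached_property
    def sagebrush_connectivity(self) -> conn.CurrentMap:
        cover = self.bundle.current_cover
        sources = cover.values >= self.window.source_threshold
        return conn.omnidirectional_current(cover, self.window, sources)

    @cached_property
    def lek_connectivity_now(self) -> conn.CurrentMap:
        cm = conn.lek_connectivity(self.bundle.current_cover, self.bundle.leks,
                                   replace(self.window, source_mode="point_based"))
        return conn.mask_lek_buffers(cm, self.bundle.leks, radius=1000.0)

    @cached_property
    def lek_connectivity_then(self) -> conn.CurrentMap:
        cm = conn.lek_connectivity(self.bundle.historic_cover, self.bundle.leks,
                                   replace(self.window, source_mode="point_based"))
        return conn.mask_lek_buffers(cm, self.bundle.leks, radius=1000.0)

    @cached_property
    def lek_connectivity_loss(self) -> RasterGrid:
        return conn.connectivity_change(self.lek_connectivity_now,
                                        self.lek_connectivity_then)

    # -- units --------------------------------------------------------------
    def base_units(self, source: str) -> PlanningUnitSet:
        cs = self.bundle.current_cover.cell_size
        if source == "intact":
            return build_units(self.intact, cs)
        if source == "degraded":
            return build_units(self.degraded, cs)
        if source == "merged":
            return build_units(self.intact | self.degraded, cs)
        raise ValueError(f"unknown planning-unit source {source!r}")


@dataclass
class RunResult:
    entry: ProblemCatalogEntry
    units: PlanningUnitSet
    spec: ProblemSpec | None
    solution: Solution
    summary: pd.DataFrame
    area_ha: float
    captures: dict[str, float]


def _assemble_spec(
    entry: ProblemCatalogEntry,
    prep: PreparedLandscape,
    prior_selection_cells: np.ndarray | None = None,
) -> tuple[PlanningUnitSet, ProblemSpec | None]:
    """Resolve an entry's recipes against prepared layers into a ProblemSpec.

    Returns (units, spec); spec is None when the unit pool is empty (the
    caller reports infeasibility)."""
    units = prep.base_units(entry.planning_unit_source)

    if entry.locked_in_recipe == "prior_solution":
        if prior_selection_cells is None:
            raise ValueError(f"entry {entry.id} needs a prior solution's cells")
        # merge prior (protection) cells into the pool so they can be locked
        mask = units.mask()
        if prior_selection_cells.size:
            mask[prior_selection_cells[:, 0], prior_selection_cells[:, 1]] = True
        units = build_units(mask, units.cell_size)

    if entry.conservation_area_mask:
        inside = prep.conservation_mask[units.cells[:, 0], units.cells[:, 1]]
        units = subset_units(units, inside)
    if entry.future_cover_threshold is not None:
        units = mask_by_future_cover(units, prep.bundle.future_cover,
                                     entry.future_cover_threshold)
    if units.n_units == 0:
        return units, None

    cost = _cost_vector(entry, prep, units)
    features = _feature_vectors(entry, prep, units)
    targets = {}
    for k in features:
        if entry.target_species is None or k == entry.target_species:
            targets[k] = Target("relative", entry.relative_target)
        else:
            targets[k] = Target("relative", 0.0)

    locked = np.empty(0, dtype=np.int64)
    if entry.locked_in_recipe == "intact":
        in_intact = prep.intact[units.cells[:, 0], units.cells[:, 1]]
        locked = np.flatnonzero(in_intact)
    elif entry.locked_in_recipe == "prior_solution" and prior_selection_cells is not None:
        idx = units.index_grid()
        locked = idx[prior_selection_cells[:, 0], prior_selection_cells[:, 1]]
        locked = locked[locked >= 0]

    spec = ProblemSpec(units=units, cost=cost, features=features, targets=targets,
                       boundary_penalty=entry.boundary_penalty,
                       edge_factor=entry.edge_factor, locked_in=locked, gap=entry.gap)
    return units, spec


def _cost_vector(entry: ProblemCatalogEntry, prep: PreparedLandscape,
                 units: PlanningUnitSet) -> np.ndarray:
    r = entry.cost_recipe
    if r == "uniform":
        return np.ones(units.n_units)
    if r == "transposed_sagebrush_connectivity":
        return transpose_max(units.extract(prep.sagebrush_connectivity.values))
    if r == "transposed_future_cover":
        return transpose_max(units.extract(prep.bundle.future_cover))
    if r == "soil_moisture":
        return units.extract(prep.bundle.soil_moisture)
    if r == "transposed_soil_moisture":
        return transpose_max(units.extract(prep.bundle.soil_moisture))
    if r == "transposed_lek_connectivity":
        return transpose_max(units.extract(prep.lek_connectivity_now.values))
    if r == "shifted_connectivity_loss":
        return shift_positive(units.extract(prep.lek_connectivity_loss))
    raise ValueError(f"unknown cost recipe {r!r}")


def _feature_vectors(entry: ProblemCatalogEntry, prep: PreparedLandscape,
                     units: PlanningUnitSet) -> dict[str, np.ndarray]:
    names = [s.name for s in prep.bundle.species_specs]
    if entry.require_cv:
        names = [s.name for s in prep.bundle.species_specs if s.has_cv]
    out: dict[str, np.ndarray] = {}
    rc, cc = units.cells[:, 0], units.cells[:, 1]
    for k in names:
        if entry.feature_recipe == "direct":
            out[k] = units.extract(prep.rescaled_features[k])
        else:
            # ecological potential on degraded cells; direct values on any
            # intact cells in the pool (merged pools / locked prior sites);
            # undefined imputations contribute 0 (excluded from totals)
            pot = prep.potential_features[k]
            vals = np.where(pot.nodata_mask[rc, cc], 0.0, pot.values[rc, cc])
            in_intact = prep.intact[rc, cc]
            direct = prep.rescaled_features[k].values[rc, cc]
            out[k] = np.where(in_intact, direct, vals)
    if entry.include_lek_abundance:
        out["lek_abundance"] = units.extract(prep.rescaled_features["lek_abundance"])
    return out


def _cv_vectors(entry: ProblemCatalogEntry, prep: PreparedLandscape,
                units: PlanningUnitSet, features: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Per-unit uncertainty for each feature, on the feature's own scale.

    The stored CV surfaces are dimensionless sd/mean ratios; the subtractive
    utility penalty needs an uncertainty expressed in the (rescaled) units
    of the feature it discounts, so each feature's penalty surface is
    CV x feature value — i.e. the standard deviation of the feature on the
    optimization scale.
    """
    out = {}
    for k, f in features.items():
        cv_grid = prep.feature_cv.get(k)
        if cv_grid is None:
            raise ValueError(f"feature {k!r} has no CV layer")
        out[k] = units.extract(cv_grid) * f
    return out


def run_catalog_problem(
    entry: ProblemCatalogEntry,
    prep: PreparedLandscape,
    backend: str = "milp",
    prior_selection_cells: np.ndarray | None = None,
) -> RunResult:
    """Assemble and solve one catalog problem; returns solution + summary."""
    units, spec = _assemble_spec(entry, prep, prior_selection_cells)
    if spec is None:
        warnings.warn(f"problem {entry.id}: empty planning-unit pool "
                      f"(mask leaves no available sites); infeasible")
        from .minset import _infeasible
        empty_spec = ProblemSpec(units=units, cost=np.empty(0), features={},
                                 targets={}, boundary_penalty=entry.boundary_penalty,
                                 edge_factor=entry.edge_factor, gap=entry.gap)
        sol = _infeasible(empty_spec, ["<empty planning-unit pool>"])
        return RunResult(entry, units, None, sol, pd.DataFrame(), 0.0, {})
    sol = solve(spec, backend=backend)
    layers = {"cost": spec.cost, **spec.features}
    summary, area_ha = summarize_solution(sol, layers, units.cell_size)
    captures = capture_report(sol, spec.features)
    return RunResult(entry, units, spec, sol, summary, area_ha, captures)


# ---------------------------------------------------------------------------
# Uncertainty sweep
# ---------------------------------------------------------------------------

@dataclass
class SensitivityMap:
    """Per-unit selection counts across the sweep, with robustness classes.

    Classes follow the selected-sites convention: 'low' sensitivity when a
    unit is selected in >= 7 iterations, 'medium' for 4-6, 'high' for 1-3,
    and 'never' for units never selected (kept separate because the
    classification compares selected sites only).
    """

    counts: np.ndarray
    n_iterations: int
    n_feasible: int

    LOW_MIN = 7
    MEDIUM_MIN = 4

    def classes(self) -> np.ndarray:
        out = np.full(self.counts.shape, "never", dtype=object)
        out[(self.counts >= 1) & (self.counts <= self.MEDIUM_MIN - 1)] = "high"
        out[(self.counts >= self.MEDIUM_MIN) & (self.counts <= self.LOW_MIN - 1)] = "medium"
        out[self.counts >= self.LOW_MIN] = "low"
        return out

    def class_counts(self) -> dict[str, int]:
        cls = self.classes()
        return {c: int((cls == c).sum()) for c in ("low", "medium", "high", "never")}


@dataclass
class SweepResult:
    sensitivity: SensitivityMap
    solutions: list[Solution]
    weights: tuple[float, ...]
    frozen_targets: dict[str, float]
    feasible: list[bool]
    units: PlanningUnitSet


def uncertainty_sweep(
    entry: ProblemCatalogEntry,
    prep: PreparedLandscape,
    weights: tuple[float, ...] = DEFAULT_SWEEP_WEIGHTS,
    backend: str = "milp",
) -> SweepResult:
    """Sweep CV penalty weights and classify per-unit selection robustness.

    Absolute targets are frozen once from the unpenalized layers
    (t_k = relative_target * total f_k), then each weight w builds utility
    layers (cost + w*CV; max(0, feature - w*CV)) and re-solves with those
    static targets.  No boundary penalty and no locked-in units (both would
    change with w and break comparability).  Infeasible iterations are
    recorded and excluded from the counts.
    """
    if entry.boundary_penalty != 0.0 or entry.locked_in_recipe != "none":
        raise ValueError("uncertainty sweep requires no boundary penalty and no locked-in units")
    units, spec = _assemble_spec(entry, prep)
    if spec is None:
        raise ValueError("uncertainty sweep on an empty planning-unit pool")
    cost_cv = units.extract(prep.bundle.soil_moisture_cv)
    feat_cv = _cv_vectors(entry, prep, units, spec.features)
    frozen = {k: entry.relative_target * float(f.sum()) for k, f in spec.features.items()}

    counts = np.zeros(units.n_units, dtype=np.int64)
    sols: list[Solution] = []
    feas: list[bool] = []
    for w in weights:
        c_u = utility_cost(spec.cost, cost_cv, w)
        f_u = {k: utility_feature(f, feat_cv[k], w) for k, f in spec.features.items()}
        s = ProblemSpec(units=units, cost=c_u, features=f_u,
                        targets={k: Target("absolute", t) for k, t in frozen.items()},
                        boundary_penalty=0.0, edge_factor=entry.edge_factor, gap=entry.gap)
        sol = solve(s, backend=backend)
        sols.append(sol)
        ok = sol.status != "infeasible"
        feas.append(ok)
        if ok:
            counts += sol.selected
    n_feas = sum(feas)
    if n_feas < len(weights):
        warnings.warn(f"{len(weights) - n_feas} sweep iteration(s) infeasible; "
                      "counts cover feasible iterations only")
    return SweepResult(
        sensitivity=SensitivityMap(counts=counts, n_iterations=len(weights),
                                   n_feasible=n_feas),
        solutions=sols, weights=tuple(weights), frozen_targets=frozen,
        feasible=feas, units=units)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def summarize_solution(
    solution: Solution,
    layers: dict[str, np.ndarray],
    cell_size: float,
) -> tuple[pd.DataFrame, float]:
    """Order statistics of each layer over selected units, plus area.

    Returns (DataFrame with median/Q1/Q3/min/max per layer, area in
    hectares).  An empty selection yields an empty frame and zero area.
    """
    sel = solution.selected
    area_ha = float(sel.sum()) * cell_size ** 2 / 1e4
    if not sel.any() or not layers:
        return pd.DataFrame(columns=["median", "q1", "q3", "min", "max"]), area_ha
    rows = {}
    for name, vals in layers.items():
        v = np.asarray(vals)[sel]
        rows[name] = {
            "median": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
            "min": float(v.min()),
            "max": float(v.max()),
        }
    return pd.DataFrame(rows).T[["median", "q1", "q3", "min", "max"]], area_ha


def overlap_report(solution: Solution, units: PlanningUnitSet,
                   polygons: PolygonLayer, template: RasterGrid) -> float:
    """Percent of selected cells whose centers fall inside the polygon set."""
    sel_cells = units.cells[solution.selected]
    if sel_cells.shape[0] == 0:
        return 0.0
    x0, y0 = template.origin
    cs = template.cell_size
    xs = x0 + (sel_cells[:, 1] + 0.5) * cs
    ys = y0 - (sel_cells[:, 0] + 0.5) * cs
    inside = shapely.contains_xy(polygons.union(), xs, ys)
    return 100.0 * float(inside.sum()) / sel_cells.shape[0]


def umbrella_matrix(
    prep: PreparedLandscape,
    species: list[str] | None = None,
    backend: str = "milp",
) -> pd.DataFrame:
    """Cross-capture matrix for the umbrella-species question.

    Rows are single-species protection runs (plus the all-species run);
    columns are species; each cell is the proportion of the column species'
    total captured by the row's solution.  Feasible diagonals are >= the
    relative target by construction.
    """
    base = default_catalog()["1a"]
    if species is None:
        species = [s.name for s in prep.bundle.species_specs]
    rows = {}
    for sp in species:
        res = run_catalog_problem(single_species_entry(base, sp), prep, backend=backend)
        rows[sp] = res.captures
    res_all = run_catalog_problem(base, prep, backend=backend)
    rows["all_species"] = res_all.captures
    return pd.DataFrame(rows).T[species]


def scd_chain(prep: PreparedLandscape, backend: str = "milp") -> dict[str, RunResult]:
    """Run the conservation-design chain: 3a, then 3b and 3c with 3a's
    selected cells locked in."""
    cat = default_catalog()
    out: dict[str, RunResult] = {}
    res3a = run_catalog_problem(cat["3a"], prep, backend=backend)
    out["3a"] = res3a
    prior = res3a.units.cells[res3a.solution.selected]
    for pid in ("3b", "3c"):
        out[pid] = run_catalog_problem(cat[pid], prep, backend=backend,
                                       prior_selection_cells=prior)
    return out
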