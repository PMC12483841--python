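"""Planning units, degradation/intactness classification, and the layer
transforms that prepare cost and feature inputs for optimization.

Planning units are eligible 30-m-style raster cells with rook adjacency and
edge-length bookkeeping (needed by boundary penalties).  Classification
splits the landscape into *degraded* cells (cover loss far above the mean
change from historic or ecological-potential cover) and *intact* cells
(not degraded, current cover at or above a threshold).  The transforms are
the standard cost/feature preprocessing steps: order-reversing transposition
so that low cost selects high values, positive-shifting of signed layers,
and CV-weighted utility layers for uncertainty analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodata import (
    PolygonLayer,
    RasterGrid,
    require_aligned,
    zonal_mean,
)

__all__ = [
    "PlanningUnitSet",
    "build_units",
    "subset_units",
    "classify_degraded",
    "classify_intact",
    "mask_by_future_cover",
    "transpose_max",
    "shift_positive",
    "utility_cost",
    "utility_feature",
    "ecological_potential",
    "INTACT_COVER_THRESHOLD",
]

#: minimum percent sagebrush cover for a cell to count as intact habitat
INTACT_COVER_THRESHOLD = 15.0


@dataclass
class PlanningUnitSet:
    """Eligible grid cells with areas and rook-adjacency edge bookkeeping.

    Attributes
    ----------
    cells : (n, 2) int array of (row, col) per unit, in row-major order.
    cell_size : metres per cell side.
    adjacency : (m, 2) int array of unit-index pairs (i < j), rook neighbors;
        every adjacent pair shares one edge of length ``cell_size``.
    study_edge_length : per-unit length of edges bordering ineligible or
        outside cells; perimeter accounting gives
        4 * cell_size = (shared edges) + study_edge_length for every unit.
    grid_shape : shape of the parent grid (for rasterizing selections).
    """

    cells: np.ndarray
    cell_size: float
    adjacency: np.ndarray
    study_edge_length: np.ndarray
    grid_shape: tuple[int, int]

    @property
    def n_units(self) -> int:
        return self.cells.shape[0]

    @property
    def area_per_unit(self) -> float:
        """Hectares per unit (cell_size^2 / 10^4)."""
        return self.cell_size ** 2 / 1e4

    @property
    def perimeter_per_unit(self) -> float:
        return 4.0 * self.cell_size

    @property
    def shared_edge_length(self) -> float:
        """Length of the edge shared by one adjacent pair."""
        return self.cell_size

    def mask(self) -> np.ndarray:
        """Boolean grid, True at unit cells."""
        m = np.zeros(self.grid_shape, dtype=bool)
        if self.n_units:
            m[self.cells[:, 0], self.cells[:, 1]] = True
        return m

    def index_grid(self) -> np.ndarray:
        """Int grid mapping cells to unit index (-1 where not a unit)."""
        g = np.full(self.grid_shape, -1, dtype=np.int64)
        if self.n_units:
            g[self.cells[:, 0], self.cells[:, 1]] = np.arange(self.n_units)
        return g

    def extract(self, grid: RasterGrid) -> np.ndarray:
        """Per-unit values read off an aligned raster."""
        if grid.shape != self.grid_shape:
            raise ValueError("raster shape does not match unit grid")
        return grid.values[self.cells[:, 0], self.cells[:, 1]]

    def rasterize(self, per_unit: np.ndarray, template: RasterGrid,
                  fill: float = 0.0, tag: str = "") -> RasterGrid:
        """Scatter per-unit values back onto the template grid."""
        vals = np.full(self.grid_shape, fill, dtype=np.float64)
        vals[self.cells[:, 0], self.cells[:, 1]] = per_unit
        mask = ~self.mask()
        return template.copy(values=vals, nodata_mask=mask, semantic_tag=tag)


def _units_from_mask(eligible: np.ndarray, cell_size: float) -> PlanningUnitSet:
    cells = np.argwhere(eligible)
    idx = np.full(eligible.shape, -1, dtype=np.int64)
    if cells.size:
        idx[cells[:, 0], cells[:, 1]] = np.arange(cells.shape[0])
    pairs = []
    # rook edges: right and down neighbors only, so each pair appears once
    a = idx[:, :-1]; b = idx[:, 1:]
    m = (a >= 0) & (b >= 0)
    pairs.append(np.column_stack([a[m], b[m]]))
    a = idx[:-1, :]; b = idx[1:, :]
    m = (a >= 0) & (b >= 0)
    pairs.append(np.column_stack([a[m], b[m]]))
    adjacency = np.vstack(pairs) if pairs else np.empty((0, 2), dtype=np.int64)
    adjacency = np.sort(adjacency, axis=1)
    n = cells.shape[0]
    degree = np.zeros(n, dtype=np.int64)
    if adjacency.size:
        np.add.at(degree, adjacency[:, 0], 1)
        np.add.at(degree, adjacency[:, 1], 1)
    study_edge = cell_size * (4 - degree).astype(np.float64)
    return PlanningUnitSet(
        cells=cells, cell_size=cell_size, adjacency=adjacency,
        study_edge_length=study_edge, grid_shape=eligible.shape)


def build_units(eligible: np.ndarray, cell_size: float) -> PlanningUnitSet:
    """Planning units from a boolean eligibility grid.

    Raises
    ------
    ValueError
        If no cell is eligible (an empty candidate pool at build time is a
        configuration error; masking an existing set may legally empty it,
        see :func:`subset_units`).
    """
    eligible = np.asarray(eligible, dtype=bool)
    if not eligible.any():
        raise ValueError("no eligible cells: cannot build a planning-unit set")
    return _units_from_mask(eligible, cell_size)


def subset_units(units: PlanningUnitSet, keep: np.ndarray) -> PlanningUnitSet:
    """Restrict a unit set to ``keep`` (boolean per unit); may be empty."""
    keep = np.asarray(keep, dtype=bool)
    if keep.shape[0] != units.n_units:
        raise ValueError("keep must have one entry per unit")
    mask = np.zeros(units.grid_shape, dtype=bool)
    if keep.any():
        kept = units.cells[keep]
        mask[kept[:, 0], kept[:, 1]] = True
    return _units_from_mask(mask, units.cell_size)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_degraded(
    historic: RasterGrid,
    potential: RasterGrid,
    current: RasterGrid,
) -> np.ndarray:
    """Degraded-cell mask from cover change relative to historic and
    ecological-potential baselines.

    Let dh = historic - current and dp = potential - current (signed: gains
    are negative losses).  With mean/SD of each change field over all
    non-nodata cells, a cell is degraded iff

    * dh >= mean_h + 2 sd_h, or
    * dp >= mean_p + 2 sd_p, or
    * both changes lie in their own one-to-two-SD band
      (mean + sd <= d < mean + 2 sd).
    """
    require_aligned(historic, potential, current)
    valid = ~(historic.nodata_mask | potential.nodata_mask | current.nodata_mask)
    dh = historic.values - current.values
    dp = potential.values - current.values
    mh, sh = dh[valid].mean(), dh[valid].std()
    mp, sp = dp[valid].mean(), dp[valid].std()
    if sh == 0 and sp == 0:
        raise ValueError("both change fields have zero variance: no classification possible")
    two_h = dh >= mh + 2 * sh
    two_p = dp >= mp + 2 * sp
    band_h = (dh >= mh + sh) & (dh < mh + 2 * sh)
    band_p = (dp >= mp + sp) & (dp < mp + 2 * sp)
    degraded = (two_h | two_p | (band_h & band_p)) & valid
    return degraded


def classify_intact(
    current: RasterGrid,
    degraded: np.ndarray,
    threshold: float = INTACT_COVER_THRESHOLD,
) -> np.ndarray:
    """Intact-cell mask: not degraded, cover >= threshold, not nodata."""
    valid = ~current.nodata_mask
    return valid & ~degraded & (current.values >= threshold)


def mask_by_future_cover(
    units: PlanningUnitSet,
    future_cover: RasterGrid,
    threshold: float | None,
) -> PlanningUnitSet:
    """Restrict units to cells projected to retain ``threshold`` percent
    cover (None = no restriction).  An empty result is legal — downstream
    solving reports it as infeasible rather than failing here."""
    if threshold is None:
        return units
    per_unit = units.extract(future_cover)
    keep = per_unit >= threshold
    nod = future_cover.nodata_mask[units.cells[:, 0], units.cells[:, 1]]
    keep &= ~nod
    return subset_units(units, keep)


# ---------------------------------------------------------------------------
# Layer transforms
# ---------------------------------------------------------------------------

def transpose_max(values: np.ndarray) -> np.ndarray:
    """Order-reversing transposition: v' = -v + v_max + 1.

    Maps the maximum to exactly 1, so a minimum-set objective preferentially
    selects high-valued cells.  v_max is taken over the values passed in
    (i.e. over the candidate planning units only).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("transpose_max needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return -v + v.max() + 1.0


def shift_positive(values: np.ndarray) -> np.ndarray:
    """Order-preserving positive shift: v' = v + |v_min| + 1.

    Used for signed layers (e.g. connectivity loss, which is <= 0) so that
    all cost values are >= 1.  Applied verbatim even when the input is
    already positive (the stated formula over cleverness).
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("shift_positive needs at least one value")
    if not np.all(np.isfinite(v)):
        raise ValueError("values must be finite")
    return v + abs(v.min()) + 1.0


def utility_cost(cost: np.ndarray, cost_cv: np.ndarray, w: float) -> np.ndarray:
    """Risk-averse cost utility: cost + w * CV (uncertain cells look dearer)."""
    if w < 0:
        raise ValueError("penalty weight must be >= 0")
    return np.asarray(cost, dtype=np.float64) + w * np.asarray(cost_cv, dtype=np.float64)


def utility_feature(feature: np.ndarray, feature_cv: np.ndarray, w: float) -> np.ndarray:
    """Risk-averse feature utility: max(0, feature - w * CV).

    Negative results are reclassified to zero (an uncertain feature value
    cannot count negatively toward a target).
    """
    if w < 0:
        raise ValueError("penalty weight must be >= 0")
    out = np.asarray(feature, dtype=np.float64) - w * np.asarray(feature_cv, dtype=np.float64)
    return np.maximum(out, 0.0)


def ecological_potential(
    feature: RasterGrid,
    intact: np.ndarray,
    clusters: PolygonLayer,
    degraded: np.ndarray,
) -> RasterGrid:
    """Impute the restored value of degraded cells from intact neighbors.

    For each management cluster, the zonal mean of ``feature`` over intact
    cells is assigned to every degraded cell in that cluster.  Degraded
    cells in clusters with no intact cells stay nodata (undefined) and are
    excluded from that feature's totals downstream.
    """
    from .geodata import polygon_membership

    means = zonal_mean(feature, clusters, within_mask=intact)
    members = polygon_membership(clusters, feature)
    vals = np.zeros(feature.shape)
    defined = np.zeros(feature.shape, dtype=bool)
    for pid in clusters.ids:
        if means[pid] is None:
            continue
        sel = members[pid] & degraded
        vals[sel] = means[pid]
        defined |= sel
    nodata = ~(defined & degraded)
    return feature.copy(values=vals, nodata_mask=nodata,
                        semantic_tag=f"ecological potential of {feature.semantic_tag}")
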