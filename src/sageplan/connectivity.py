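"""Omnidirectional circuit-theory connectivity.

Movement potential is modeled as electrical current through a resistor
network: each raster cell with positive conductance is a node, rook
neighbors are joined by a resistor whose conductance is the arithmetic mean
of the two cells' conductances, and a unit current injected at a source cell
flows to a set of grounded cells.  Solving the Kirchhoff node equations in a
moving window around each source and accumulating per-cell throughflow
current over all windows yields an omnidirectional cumulative current map —
high current marks pinch points and corridors.

Two source schemes are supported: *cover-based* (every cell at or above a
cover threshold is a source; within each window the center is injected and
the other sources are grounded) and *point-based* (e.g. sage-grouse lek
locations; each lek is injected against the other leks in its window).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu, spsolve

from .geodata import PointLayer, RasterGrid, buffer_mask, require_aligned

__all__ = [
    "WindowConfig",
    "CurrentMap",
    "solve_window",
    "omnidirectional_current",
    "lek_connectivity",
    "mask_lek_buffers",
    "connectivity_change",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowConfig:
    """Moving-window configuration.

    radius: window radius in metres (default 30 km, an annual-home-range
    scale for sage-grouse).  source_threshold: percent cover at which a cell
    counts as a source when source_mode is 'cover_based' (default 15, the
    intact-habitat definition).  stride: thinning of window centers in cells
    (1 = every source is a window center); a desk-scale control that leaves
    the per-window physics unchanged.  equal_source_strength: unit current
    injection at every window center.
    """

    radius: float = 30_000.0
    source_threshold: float = 15.0
    stride: int = 1
    source_mode: str = "cover_based"
    equal_source_strength: bool = True
    neighbors: int = 4

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.source_mode not in ("cover_based", "point_based"):
            raise ValueError(f"unknown source_mode {self.source_mode!r}")
        if self.neighbors not in (4, 8):
            raise ValueError("neighbors must be 4 or 8")


@dataclass
class CurrentMap:
    """Cumulative (or focal-mean) current surface with its provenance."""

    values: RasterGrid
    config: WindowConfig
    conductance_tag: str = ""

    def compatible_with(self, other: "CurrentMap") -> bool:
        return self.config == other.config


def _window_graph(conductance: np.ndarray, neighbors: int = 4):
    """Sparse symmetric conductance matrix on positive-conductance cells.

    Returns (node_index_grid, W) where W[i, j] is the edge conductance
    (arithmetic mean of the two cell conductances).
    """
    pos = conductance > 0
    idx = np.full(conductance.shape, -1, dtype=np.int64)
    idx[pos] = np.arange(pos.sum())
    rows, cols, vals = [], [], []
    shifts = [(0, 1), (1, 0)]
    if neighbors == 8:
        shifts += [(1, 1), (1, -1)]
    for dr, dc in shifts:
        a_sl = (slice(0, conductance.shape[0] - dr), slice(max(0, -dc), conductance.shape[1] - max(0, dc)))
        b_sl = (slice(dr, conductance.shape[0]), slice(max(0, dc), conductance.shape[1] - max(0, -dc)))
        ia, ib = idx[a_sl], idx[b_sl]
        ca, cb = conductance[a_sl], conductance[b_sl]
        m = (ia >= 0) & (ib >= 0)
        rows.append(ia[m]); cols.append(ib[m]); vals.append(0.5 * (ca[m] + cb[m]))
    r = np.concatenate(rows); c = np.concatenate(cols); v = np.concatenate(vals)
    n = int(pos.sum())
    W = coo_matrix((np.concatenate([v, v]), (np.concatenate([r, c]), np.concatenate([c, r]))),
                   shape=(n, n)).tocsr()
    return idx, W


def solve_window(
    conductance_patch: np.ndarray,
    source_cell: tuple[int, int],
    ground_cells: list[tuple[int, int]],
    injection: float = 1.0,
    neighbors: int = 4,
) -> tuple[np.ndarray, float]:
    """Solve one resistor-network window.

    Injects ``injection`` current at the source cell, grounds the ground
    set (potential 0), solves the Kirchhoff node equations, and returns
    (per-cell throughflow current, net current absorbed at the grounds).
    A window with no positive-conductance path from source to any ground
    carries zero current (logged, not fatal).
    """
    patch = np.asarray(conductance_patch, dtype=np.float64)
    if np.any(patch < 0):
        raise ValueError("conductance must be >= 0")
    out = np.zeros(patch.shape)
    sr, sc = source_cell
    if patch[sr, sc] <= 0:
        return out, 0.0
    grounds = [(r, c) for (r, c) in ground_cells if patch[r, c] > 0 and (r, c) != (sr, sc)]
    if not grounds:
        return out, 0.0
    idx, W = _window_graph(patch, neighbors)
    n = W.shape[0]
    src = idx[sr, sc]
    # restrict to the source's connected component
    ncomp, labels = connected_components(W, directed=False)
    comp = labels == labels[src]
    gset = np.array([idx[r, c] for (r, c) in grounds], dtype=np.int64)
    gset = gset[comp[gset]]
    if gset.size == 0:
        log.debug("window source has no path to any ground; zero current")
        return out, 0.0

    keep = comp.copy()
    keep[gset] = False  # grounds held at potential 0
    keep_idx = np.flatnonzero(keep)
    pos_in_reduced = np.full(n, -1, dtype=np.int64)
    pos_in_reduced[keep_idx] = np.arange(keep_idx.size)

    Wk = W[keep_idx][:, keep_idx]
    deg_full = np.asarray(W.sum(axis=1)).ravel()  # includes edges to grounds
    L = csr_matrix(
        (deg_full[keep_idx], (np.arange(keep_idx.size), np.arange(keep_idx.size))),
        shape=(keep_idx.size, keep_idx.size)) - Wk
    b = np.zeros(keep_idx.size)
    b[pos_in_reduced[src]] = injection
    v_red = splu(L.tocsc()).solve(b)

    volt = np.zeros(n)
    volt[keep_idx] = v_red  # grounds and off-component nodes stay 0

    # per-node throughflow: half the sum of absolute edge currents plus half
    # the absolute injected/absorbed current (standard current-map rule)
    Wcoo = W.tocoo()
    m = Wcoo.row < Wcoo.col
    er, ec, ew = Wcoo.row[m], Wcoo.col[m], Wcoo.data[m]
    on_comp = comp[er]
    er, ec, ew = er[on_comp], ec[on_comp], ew[on_comp]
    edge_cur = ew * (volt[er] - volt[ec])
    node_flow = np.zeros(n)
    np.add.at(node_flow, er, np.abs(edge_cur))
    np.add.at(node_flow, ec, np.abs(edge_cur))
    injected = np.zeros(n)
    injected[src] = abs(injection)
    # current absorbed at each ground = net signed flow into it
    net_in = np.zeros(n)
    np.add.at(net_in, ec, edge_cur)   # positive edge current flows er -> ec
    np.add.at(net_in, er, -edge_cur)
    absorbed_each = np.zeros(n)
    absorbed_each[gset] = net_in[gset]
    node_current = 0.5 * (node_flow + injected + np.abs(absorbed_each))
    rr, cc = np.nonzero(idx >= 0)
    out[rr, cc] = node_current[idx[rr, cc]]
    return out, float(absorbed_each.sum())


def _source_cells_from_points(points: PointLayer, template: RasterGrid) -> np.ndarray:
    """Map points to the (row, col) of the containing cell; drops points
    outside the grid."""
    x0, y0 = template.origin
    cs = template.cell_size
    cols = np.floor((points.points[:, 0] - x0) / cs).astype(int)
    rows = np.floor((y0 - points.points[:, 1]) / cs).astype(int)
    ok = (rows >= 0) & (rows < template.shape[0]) & (cols >= 0) & (cols < template.shape[1])
    return np.column_stack([rows[ok], cols[ok]])


def omnidirectional_current(
    conductance: RasterGrid,
    config: WindowConfig,
    sources: np.ndarray | PointLayer,
) -> CurrentMap:
    """Cumulative current from moving-window solves at every source.

    cover_based: ``sources`` is a boolean grid (e.g. cover >= threshold);
    each source cell on the stride lattice becomes a window center, grounded
    against the other sources inside its window.  point_based: ``sources``
    is a PointLayer; each point is a window center grounded against the
    other points in its window.  Accumulation is order-independent (a sum).
    """
    cs = conductance.cell_size
    R = max(1, int(round(config.radius / cs)))
    cond = conductance.values.copy()
    cond[conductance.nodata_mask] = 0.0
    acc = np.zeros(conductance.shape)

    if isinstance(sources, PointLayer):
        centers = _source_cells_from_points(sources, conductance)
        source_grid = np.zeros(conductance.shape, dtype=bool)
        if centers.size:
            source_grid[centers[:, 0], centers[:, 1]] = True
    else:
        source_grid = np.asarray(sources, dtype=bool)
        centers = np.argwhere(source_grid)
        if config.stride > 1:
            on_lattice = (centers[:, 0] % config.stride == 0) & (centers[:, 1] % config.stride == 0)
            centers = centers[on_lattice]

    if centers.size == 0:
        warnings.warn("no sources: connectivity map is all zero")
        return CurrentMap(conductance.copy(values=acc, nodata_mask=np.zeros(conductance.shape, bool),
                                           semantic_tag="cumulative current"),
                          config, conductance.semantic_tag)

    nrow, ncol = conductance.shape
    for (r, c) in centers:
        r0, r1 = max(0, r - R), min(nrow, r + R + 1)
        c0, c1 = max(0, c - R), min(ncol, c + R + 1)
        patch = cond[r0:r1, c0:c1]
        sub_sources = source_grid[r0:r1, c0:c1].copy()
        sub_sources[r - r0, c - c0] = False
        grounds = [tuple(p) for p in np.argwhere(sub_sources)]
        cur, _ = solve_window(patch, (r - r0, c - c0), grounds,
                              injection=1.0, neighbors=config.neighbors)
        acc[r0:r1, c0:c1] += cur

    grid = conductance.copy(values=acc, nodata_mask=np.zeros(conductance.shape, bool),
                            semantic_tag="cumulative current")
    return CurrentMap(grid, config, conductance.semantic_tag)


def _focal_mean(values: np.ndarray, radius_cells: int) -> np.ndarray:
    """Mean over a circular neighborhood, truncated at the grid edge."""
    yy, xx = np.mgrid[-radius_cells:radius_cells + 1, -radius_cells:radius_cells + 1]
    disk = (yy ** 2 + xx ** 2) <= radius_cells ** 2
    kernel = disk.astype(np.float64)
    num = ndimage.convolve(values, kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(np.ones_like(values), kernel, mode="constant", cval=0.0)
    return num / den


def lek_connectivity(
    conductance: RasterGrid,
    leks: PointLayer,
    config: WindowConfig | None = None,
) -> CurrentMap:
    """Lek-to-lek connectivity: point-based omnidirectional current followed
    by a focal mean over the window radius.

    The focal-mean step interprets the final map as "mean values over the
    moving window"; it smooths the cumulative surface at the same scale the
    windows used.
    """
    if len(leks) < 2:
        raise ValueError("lek connectivity needs at least 2 leks")
    cfg = config or WindowConfig(source_mode="point_based")
    if cfg.source_mode != "point_based":
        cfg = WindowConfig(radius=cfg.radius, source_threshold=cfg.source_threshold,
                           stride=cfg.stride, source_mode="point_based",
                           equal_source_strength=cfg.equal_source_strength,
                           neighbors=cfg.neighbors)
    cum = omnidirectional_current(conductance, cfg, leks)
    R = max(1, int(round(cfg.radius / conductance.cell_size)))
    smoothed = _focal_mean(cum.values.values, R)
    grid = cum.values.copy(values=smoothed, semantic_tag="lek connectivity (focal mean current)")
    return CurrentMap(grid, cfg, conductance.semantic_tag)


def mask_lek_buffers(current: CurrentMap, leks: PointLayer, radius: float = 1000.0) -> CurrentMap:
    """Zero the current surface within ``radius`` of any lek (those sites
    are assumed already protected; their extreme near-source currents would
    otherwise dominate prioritization)."""
    m = buffer_mask(leks, radius, current.values)
    vals = current.values.values.copy()
    vals[m] = 0.0
    return CurrentMap(current.values.copy(values=vals), current.config, current.conductance_tag)


def connectivity_change(now: CurrentMap, then: CurrentMap) -> RasterGrid:
    """Loss-only connectivity change: min(now - then, 0).

    Positive change can arise from mere current redirection, so gains are
    clamped to zero and the layer reflects predicted loss only.  Both maps
    must come from identically configured runs.
    """
    if not now.compatible_with(then):
        raise ValueError("connectivity maps come from differently configured runs")
    require_aligned(now.values, then.values)
    change = np.minimum(now.values.values - then.values.values, 0.0)
    return now.values.copy(values=change, semantic_tag="connectivity loss (change <= 0)")
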