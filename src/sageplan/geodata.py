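"""Raster/vector data model, I/O and generic spatial operators.

All layers in one analysis live on a single north-up grid: square cells of
``cell_size`` metres, ``origin`` at the map coordinates of the top-left
corner, row 0 at the top.  Grid indexing is (row, col), 0-based; map
coordinates are metres.  Rasters are stored as GeoTIFF (single band, declared
nodata), polygon and point layers as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping as geom_mapping, shape as geom_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "RasterGrid",
    "PolygonLayer",
    "PointLayer",
    "AlignmentError",
    "require_aligned",
    "read_raster",
    "write_raster",
    "read_polygons",
    "write_polygons",
    "read_points",
    "write_points",
    "zonal_mean",
    "buffer_mask",
    "rescale01",
    "coefficient_of_variation",
]

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


class AlignmentError(ValueError):
    """Raised when grids that must share a common grid do not."""


@dataclass
class RasterGrid:
    """A single-band, north-up raster on a square grid.

    Parameters
    ----------
    values
        2-D array, row-major, row 0 at the north edge.
    cell_size
        Side length of one cell in metres (> 0).
    origin
        Map coordinates ``(x, y)`` of the *top-left corner* of cell (0, 0).
    nodata_mask
        Boolean array, same shape as ``values``; True marks missing cells.
    semantic_tag
        Free-text description of what the values mean (e.g. "percent cover").
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]
    nodata_mask: np.ndarray | None = None
    semantic_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape must equal values shape")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self, values: np.ndarray | None = None,
             nodata_mask: np.ndarray | None = None,
             semantic_tag: str | None = None) -> "RasterGrid":
        """A grid on the same georeferenced lattice with new values/mask."""
        return RasterGrid(
            values=self.values.copy() if values is None else np.asarray(values, dtype=np.float64),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy() if nodata_mask is None else np.asarray(nodata_mask, dtype=bool),
            semantic_tag=self.semantic_tag if semantic_tag is None else semantic_tag,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every cell center, each of grid shape."""
        nrow, ncol = self.shape
        x0, y0 = self.origin
        cols = np.arange(ncol)
        rows = np.arange(nrow)
        xs = x0 + (cols + 0.5) * self.cell_size
        ys = y0 - (rows + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and self.cell_size == other.cell_size
            and self.origin == other.origin
        )


def require_aligned(*grids: RasterGrid) -> None:
    """Check that all grids share shape, cell size and origin.

    Raises
    ------
    AlignmentError
        Naming the first grid that disagrees with the first one.
    """
    if not grids:
        return
    ref = grids[0]
    for k, g in enumerate(grids[1:], start=1):
        if not ref.aligned_with(g):
            raise AlignmentError(
                f"grid {k} (shape {g.shape}, cell_size {g.cell_size}, origin {g.origin}) "
                f"is not aligned with grid 0 (shape {ref.shape}, cell_size {ref.cell_size}, "
                f"origin {ref.origin})"
            )


@dataclass
class PolygonLayer:
    """Named simple polygons with a role tag (cluster_zone | conservation_area)."""

    ids: list[str]
    polygons: list[BaseGeometry]
    role_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.polygons):
            raise ValueError("ids and polygons must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("polygon ids must be unique")
        for pid, poly in zip(self.ids, self.polygons):
            if not poly.is_valid:
                raise ValueError(f"polygon {pid!r} is invalid (self-intersecting?)")

    def __len__(self) -> int:
        return len(self.ids)

    def union(self) -> BaseGeometry:
        return shapely.union_all(self.polygons)


@dataclass
class PointLayer:
    """Point locations in map coordinates, with optional positive weights."""

    points: np.ndarray  # (n, 2) array of (x, y)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.size and self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (x, y)")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape[0] != self.points.shape[0]:
                raise ValueError("weights length must match points")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be strictly positive")

    def __len__(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path, nodata: float = DEFAULT_NODATA) -> None:
    """Write a grid as a single-band GeoTIFF with a declared nodata value.

    Masked cells are stored as ``nodata``; georeferencing goes into the
    standard ModelPixelScale / ModelTiepoint tags.
    """
    import tifffile

    out = grid.values.copy()
    out[grid.nodata_mask] = nodata
    x0, y0 = grid.origin
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (grid.cell_size, grid.cell_size, 0.0), True),
        (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0), True),
        (_GDAL_NODATA, "s", 0, repr(nodata), True),
    ]
    tifffile.imwrite(
        path, out, extratags=extratags,
        description=grid.semantic_tag or "",
        metadata=None,
    )


def read_raster(path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or any
    GeoTIFF carrying pixel-scale, tiepoint and GDAL nodata tags)."""
    import tifffile

    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise ValueError(f"{path}: expected a single-band raster, found {len(tf.pages)} pages")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError(f"{path}: expected 1 sample per pixel, found {page.samplesperpixel}")
        tags = page.tags
        if _MODEL_PIXEL_SCALE not in tags or _MODEL_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing (ModelPixelScale/ModelTiepoint tags)")
        scale = tags[_MODEL_PIXEL_SCALE].value
        tie = tags[_MODEL_TIEPOINT].value
        if abs(scale[0] - scale[1]) > 1e-9:
            raise ValueError(f"{path}: non-square cells ({scale[0]} x {scale[1]}) are not supported")
        if _GDAL_NODATA not in tags:
            raise ValueError(f"{path}: missing declared nodata value (GDAL_NODATA tag)")
        nodata = float(tags[_GDAL_NODATA].value)
        # tiepoint maps raster (0,0) corner to map (tie[3], tie[4])
        origin = (float(tie[3]), float(tie[4]))
        values = page.asarray().astype(np.float64)
        tag_text = page.description or ""
    mask = values == nodata
    if np.isnan(nodata):  # pragma: no cover - unusual but legal
        mask = np.isnan(values)
    return RasterGrid(values=values, cell_size=float(scale[0]), origin=origin,
                      nodata_mask=mask, semantic_tag=tag_text)


def write_polygons(layer: PolygonLayer, path) -> None:
    features = [
        {
            "type": "Feature",
            "properties": {"id": pid, "role": layer.role_tag},
            "geometry": geom_mapping(poly),
        }
        for pid, poly in zip(layer.ids, layer.polygons)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_polygons(path) -> PolygonLayer:
    with open(path) as fh:
        fc = json.load(fh)
    ids, polys, role = [], [], ""
    for feat in fc["features"]:
        ids.append(str(feat["properties"]["id"]))
        role = feat["properties"].get("role", role)
        polys.append(geom_shape(feat["geometry"]))
    return PolygonLayer(ids=ids, polygons=polys, role_tag=role)


def write_points(layer: PointLayer, path) -> None:
    features = []
    for i, (x, y) in enumerate(layer.points):
        props = {}
        if layer.weights is not None:
            props["weight"] = float(layer.weights[i])
        features.append({
            "type": "Feature",
            "properties": props,
            "geometry": {"type": "Point", "coordinates": [float(x), float(y)]},
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_points(path) -> PointLayer:
    with open(path) as fh:
        fc = json.load(fh)
    pts, weights = [], []
    for feat in fc["features"]:
        pts.append(feat["geometry"]["coordinates"])
        if "weight" in feat["properties"]:
            weights.append(feat["properties"]["weight"])
    w = np.asarray(weights) if weights else None
    return PointLayer(points=np.asarray(pts, dtype=np.float64).reshape(-1, 2), weights=w)


# ---------------------------------------------------------------------------
# Spatial operators
# ---------------------------------------------------------------------------

def polygon_membership(zones: PolygonLayer, template: RasterGrid) -> dict[str, np.ndarray]:
    """Boolean grid per zone id: True where the cell *center* lies in the zone.

    Cell membership is by center containment (points on a shared zone
    boundary belong to neither zone).
    """
    xs, ys = template.cell_centers()
    out: dict[str, np.ndarray] = {}
    for pid, poly in zip(zones.ids, zones.polygons):
        out[pid] = shapely.contains_xy(poly, xs, ys)
    return out


def zonal_mean(
    value_grid: RasterGrid,
    zones: PolygonLayer,
    within_mask: np.ndarray | None = None,
) -> dict[str, float | None]:
    """Arithmetic mean of ``value_grid`` per zone over eligible cells.

    A cell contributes iff its center falls in the zone, it is True in
    ``within_mask`` (if given) and it is not nodata.  Zones with no eligible
    cell map to ``None`` (undefined), never to zero.
    """
    eligible = ~value_grid.nodata_mask
    if within_mask is not None:
        if within_mask.shape != value_grid.shape:
            raise AlignmentError("within_mask shape does not match value grid")
        eligible = eligible & within_mask
    members = polygon_membership(zones, value_grid)
    out: dict[str, float | None] = {}
    for pid, inzone in members.items():
        sel = inzone & eligible
        out[pid] = float(value_grid.values[sel].mean()) if sel.any() else None
    return out


def buffer_mask(points: PointLayer, radius: float, template: RasterGrid) -> np.ndarray:
    """True where a cell center lies within ``radius`` metres of any point."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    xs, ys = template.cell_centers()
    mask = np.zeros(template.shape, dtype=bool)
    for x, y in points.points:
        mask |= (xs - x) ** 2 + (ys - y) ** 2 <= radius ** 2
    return mask


def rescale01(grid: RasterGrid) -> RasterGrid:
    """Linear rescale of the non-nodata cells to [0, 1].

    A constant layer maps to all zeros (keeps the layer usable without a
    divide-by-zero).  All-nodata input is an error.
    """
    valid = ~grid.nodata_mask
    if not valid.any():
        raise ValueError("cannot rescale an all-nodata grid")
    v = grid.values[valid]
    lo, hi = v.min(), v.max()
    out = np.zeros_like(grid.values)
    if hi > lo:
        out[valid] = (grid.values[valid] - lo) / (hi - lo)
    return grid.copy(values=out, semantic_tag=(grid.semantic_tag + " (rescaled 0-1)").strip())


def coefficient_of_variation(mean_grid: RasterGrid, sd_grid: RasterGrid) -> RasterGrid:
    """Per-cell CV = sd / mean; cells with mean <= 0 become nodata.

    CV is undefined at non-positive means; downstream treats nodata as
    ineligible.
    """
    require_aligned(mean_grid, sd_grid)
    if np.any(sd_grid.values[~sd_grid.nodata_mask] < 0):
        raise ValueError("standard deviations must be >= 0")
    bad = mean_grid.nodata_mask | sd_grid.nodata_mask | (mean_grid.values <= 0)
    out = np.zeros_like(mean_grid.values)
    good = ~bad
    out[good] = sd_grid.values[good] / mean_grid.values[good]
    return mean_grid.copy(values=out, nodata_mask=bad, semantic_tag="coefficient of variation")
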