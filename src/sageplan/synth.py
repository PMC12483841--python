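"""Seeded synthetic landscapes with the statistical structure the planning
workflow assumes.

The generator emulates the input stack of a sagebrush conservation analysis:
a cover time series (historic, ecological-potential, current, projected
future percent cover) with spatially autocorrelated structure and patchy
degradation; species feature layers with contrasting distribution shapes
(right-skewed density-like vs. left-skewed bounded-probability layers, one
species preferring open low-cover shrubland); per-layer CV uncertainty
surfaces; management cluster zones; conservation-area polygons; and lek
points placed preferentially in high-cover cells.  Everything is
bit-reproducible from (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import box

from .geodata import (
    PointLayer,
    PolygonLayer,
    RasterGrid,
    write_points,
    write_polygons,
    write_raster,
)

__all__ = [
    "SpeciesSpec",
    "BundleConfig",
    "LandscapeBundle",
    "generate_cover_series",
    "generate_features",
    "generate_zones_and_leks",
    "generate_bundle",
    "write_bundle",
    "DEFAULT_SPECIES",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """Declared response of a synthetic species to sagebrush cover.

    response: 'increasing', 'decreasing' (open-shrubland preference) or
    'hump' (intermediate-cover optimum).
    family: 'density' (non-negative, right-skewed, birds/km^2-like) or
    'probability' (bounded [0,1], left-skewed, presence/persistence-like).
    has_cv: whether an uncertainty (CV) surface accompanies the layer.
    """

    name: str
    response: str = "increasing"
    family: str = "density"
    has_cv: bool = True

    def __post_init__(self):
        if self.response not in ("increasing", "decreasing", "hump"):
            raise ValueError(f"unknown response {self.response!r}")
        if self.family not in ("density", "probability"):
            raise ValueError(f"unknown value family {self.family!r}")


# Default community: two songbird-like density layers (one preferring open,
# low-cover shrubland), a persistence-probability layer, and a
# presence-probability layer with no uncertainty surface (so it drops out of
# the uncertainty sweep, as presence-only products often must).
DEFAULT_SPECIES: tuple[SpeciesSpec, ...] = (
    SpeciesSpec("obligate_songbird", "increasing", "density", True),
    SpeciesSpec("open_shrubland_songbird", "decreasing", "density", True),
    SpeciesSpec("grouse_persistence", "increasing", "probability", True),
    SpeciesSpec("burrowing_mammal", "hump", "probability", False),
)


@dataclass(frozen=True)
class BundleConfig:
    shape: tuple[int, int] = (100, 100)
    cell_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)
    autocorr_scale: float = 6.0
    degrade_fraction: float = 0.2
    degrade_depth: float = 12.0
    n_clusters: int = 4
    n_leks: int = 12
    conservation_fraction: float = 0.5
    species: tuple[SpeciesSpec, ...] = DEFAULT_SPECIES


@dataclass
class LandscapeBundle:
    """All layers one planning analysis needs, on a common grid."""

    historic_cover: RasterGrid
    potential_cover: RasterGrid
    current_cover: RasterGrid
    future_cover: RasterGrid
    features: dict[str, RasterGrid]
    feature_cv: dict[str, RasterGrid]  # only species with has_cv
    lek_abundance: RasterGrid          # cluster-constant abundance index
    lek_abundance_cv: RasterGrid
    soil_moisture: RasterGrid
    soil_moisture_cv: RasterGrid
    cluster_zones: PolygonLayer
    conservation_areas: PolygonLayer
    leks: PointLayer
    seed: int
    config: BundleConfig

    @property
    def species_specs(self) -> tuple[SpeciesSpec, ...]:
        return self.config.species


def _smooth01(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Spatially autocorrelated field rescaled to [0, 1].

    White noise smoothed with a Gaussian kernel of the given scale (cells);
    simple, seedable, and gives the patch structure the tests need.
    """
    z = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="nearest")
    lo, hi = z.min(), z.max()
    if hi == lo:  # pragma: no cover - degenerate smoothing
        return np.zeros(shape)
    return (z - lo) / (hi - lo)


def generate_cover_series(
    seed: int,
    shape: tuple[int, int] = (100, 100),
    cell_size: float = 30.0,
    origin: tuple[float, float] = (0.0, 0.0),
    autocorr_scale: float = 6.0,
    degrade_fraction: float = 0.2,
    degrade_depth: float = 12.0,
) -> dict[str, RasterGrid]:
    """Historic / potential / current / future percent-cover grids.

    current = historic minus patchy losses covering ~``degrade_fraction`` of
    cells at depth ~``degrade_depth``; future = current attenuated by a
    smooth trend so that 5/10/15 % thresholds partition the map nontrivially.
    """
    if not (0.0 <= degrade_fraction <= 1.0):
        raise ValueError("degrade_fraction must be in [0, 1]")
    if shape[0] < 8 or shape[1] < 8:
        raise ValueError("shape must be at least 8x8")
    rng = np.random.default_rng(seed)

    base = _smooth01(rng, shape, autocorr_scale)
    historic = np.clip(8.0 + 45.0 * base, 0.0, 95.0)
    potential = np.clip(historic + 2.0 + 4.0 * _smooth01(rng, shape, autocorr_scale), 0.0, 100.0)

    current = historic.copy()
    if degrade_fraction > 0:
        dfield = _smooth01(rng, shape, autocorr_scale / 2.0)
        thr = np.quantile(dfield, 1.0 - degrade_fraction)
        patch = dfield > thr
        # depth ramps from ~0.5x to ~1.5x the nominal depth inside patches
        exceed = np.zeros(shape)
        span = dfield.max() - thr
        if span > 0:
            exceed[patch] = (dfield[patch] - thr) / span
        loss = np.where(patch, degrade_depth * (0.5 + exceed), 0.0)
        current = np.clip(historic - loss, 0.0, 100.0)

    trend = 0.25 + 0.7 * _smooth01(rng, shape, autocorr_scale * 1.5)
    future = np.clip(current * trend, 0.0, 100.0)

    def grid(vals, tag):
        return RasterGrid(vals, cell_size, origin, semantic_tag=tag)

    return {
        "historic": grid(historic, "percent cover (historic)"),
        "potential": grid(potential, "percent cover (ecological potential)"),
        "current": grid(current, "percent cover (current)"),
        "future": grid(future, "percent cover (projected future)"),
    }


def _rank_uniform(x: np.ndarray) -> np.ndarray:
    """Map values to (0, 1) by rank; preserves ordering exactly."""
    flat = x.ravel()
    order = np.argsort(flat, kind="stable")
    ranks = np.empty_like(order, dtype=np.float64)
    ranks[order] = np.arange(flat.size)
    return ((ranks + 0.5) / flat.size).reshape(x.shape)


def generate_features(
    seed: int,
    current_cover: RasterGrid,
    species_specs: tuple[SpeciesSpec, ...] = DEFAULT_SPECIES,
    autocorr_scale: float = 6.0,
) -> tuple[dict[str, RasterGrid], dict[str, RasterGrid]]:
    """Feature layers per species plus CV layers for species that have them.

    Density-family layers are non-negative and right-skewed (lognormal-style
    noise around the cover response, mimicking count-derived densities whose
    largest values far exceed the mean); probability-family layers lie in
    [0, 1] and are left-skewed (mass piled toward high values).
    """
    rng = np.random.default_rng(seed)
    cov01 = _rank_uniform(current_cover.values)
    features: dict[str, RasterGrid] = {}
    cvs: dict[str, RasterGrid] = {}
    for spec in species_specs:
        if spec.response == "increasing":
            r = cov01
        elif spec.response == "decreasing":
            r = 1.0 - cov01
        else:  # hump
            r = np.exp(-(((cov01 - 0.5) / 0.25) ** 2))
        noise = ndimage.gaussian_filter(rng.standard_normal(cov01.shape),
                                        sigma=autocorr_scale / 2.0, mode="nearest")
        noise = noise / max(noise.std(), 1e-12)
        if spec.family == "density":
            # multiplicative lognormal noise => right skew, heavy right tail
            vals = 40.0 * (0.05 + r) ** 2 * np.exp(0.8 * noise)
        else:
            # cube-root of a rank-uniformized latent => left skew in [0, 1]
            latent = 0.75 * r + 0.25 * _rank_uniform(noise)
            vals = _rank_uniform(latent) ** (1.0 / 3.0)
        features[spec.name] = current_cover.copy(
            values=vals, semantic_tag=f"{spec.name} ({spec.family})")
        if spec.has_cv:
            cv = 0.35 * _smooth01(rng, cov01.shape, autocorr_scale) + 0.05
            cvs[spec.name] = current_cover.copy(
                values=cv, semantic_tag=f"{spec.name} CV")
    return features, cvs


def generate_zones_and_leks(
    seed: int,
    template: RasterGrid,
    cover: RasterGrid,
    n_clusters: int = 4,
    n_leks: int = 12,
    conservation_fraction: float = 0.5,
) -> tuple[PolygonLayer, PolygonLayer, PointLayer]:
    """Cluster zones tiling the grid, conservation-area polygons, and leks.

    Cluster zones are a rectangular tiling (every cell center falls in
    exactly one zone).  Conservation areas are two rectangles (core and
    growth-opportunity analogues) jointly covering about
    ``conservation_fraction`` of the map.  Leks are sampled preferentially
    from high-cover cells.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    nrow, ncol = template.shape
    cs = template.cell_size
    x0, y0 = template.origin
    width, height = ncol * cs, nrow * cs

    # near-square factorization of n_clusters into a block grid
    kr = int(np.floor(np.sqrt(n_clusters)))
    while n_clusters % kr:
        kr -= 1
    kc = n_clusters // kr
    ids, polys = [], []
    for i in range(kr):
        for j in range(kc):
            xa = x0 + j * width / kc
            xb = x0 + (j + 1) * width / kc
            ya = y0 - (i + 1) * height / kr
            yb = y0 - i * height / kr
            ids.append(f"cluster_{i * kc + j}")
            polys.append(box(xa, ya, xb, yb))
    clusters = PolygonLayer(ids=ids, polygons=polys, role_tag="cluster_zone")

    # conservation areas: a large core box and a smaller growth box
    frac_core = conservation_fraction * 0.7
    frac_grow = conservation_fraction * 0.3
    def rand_box(frac):
        w = width * np.sqrt(frac) * rng.uniform(0.9, 1.3)
        h = (frac * width * height) / w
        w, h = min(w, width), min(h, height)
        xa = x0 + rng.uniform(0, width - w)
        yb = y0 - rng.uniform(0, height - h)
        return box(xa, yb - h, xa + w, yb)
    areas = PolygonLayer(
        ids=["core", "growth"],
        polygons=[rand_box(frac_core), rand_box(frac_grow)],
        role_tag="conservation_area",
    )

    # leks: preferential sampling toward high cover, located at cell centers
    w = np.exp(cover.values / 8.0).ravel()
    w /= w.sum()
    idx = rng.choice(cover.values.size, size=n_leks, replace=False, p=w)
    rows, cols = np.unravel_index(idx, cover.values.shape)
    xs = x0 + (cols + 0.5) * cs
    ys = y0 - (rows + 0.5) * cs
    leks = PointLayer(points=np.column_stack([xs, ys]))
    return clusters, areas, leks


def generate_bundle(seed: int, config: BundleConfig | None = None) -> LandscapeBundle:
    """Assemble a complete, aligned landscape bundle from one seed."""
    cfg = config or BundleConfig()
    covers = generate_cover_series(
        seed, cfg.shape, cfg.cell_size, cfg.origin, cfg.autocorr_scale,
        cfg.degrade_fraction, cfg.degrade_depth)
    features, cvs = generate_features(
        seed + 1, covers["current"], cfg.species, cfg.autocorr_scale)
    clusters, areas, leks = generate_zones_and_leks(
        seed + 2, covers["current"], covers["current"], cfg.n_clusters,
        cfg.n_leks, cfg.conservation_fraction)

    rng = np.random.default_rng(seed + 3)
    # soil moisture: autocorrelated, loosely coupled to cover, strictly > 0
    sm = 0.2 + 0.6 * _smooth01(rng, cfg.shape, cfg.autocorr_scale) \
        + 0.2 * covers["current"].values / 100.0
    sm_cv = 0.3 * _smooth01(rng, cfg.shape, cfg.autocorr_scale) + 0.05
    template = covers["current"]
    soil = template.copy(values=sm, semantic_tag="spring soil moisture availability")
    soil_cv = template.copy(values=sm_cv, semantic_tag="spring soil moisture CV")

    # lek-abundance index: constant within each management cluster (the
    # abundance product is estimated at cluster scale, then rasterized)
    from .geodata import polygon_membership
    members = polygon_membership(clusters, template)
    ab = np.zeros(cfg.shape)
    ab_cv = np.zeros(cfg.shape)
    for pid in clusters.ids:
        inz = members[pid]
        mean_cov = covers["current"].values[inz].mean() if inz.any() else 0.0
        level = (5.0 + mean_cov) * rng.lognormal(0.0, 0.4)
        ab[inz] = level
        ab_cv[inz] = rng.uniform(0.1, 0.5)
    lek_ab = template.copy(values=ab, semantic_tag="mean lek abundance (cluster level)")
    lek_ab_cv = template.copy(values=ab_cv, semantic_tag="mean lek abundance CV")

    return LandscapeBundle(
        historic_cover=covers["historic"],
        potential_cover=covers["potential"],
        current_cover=covers["current"],
        future_cover=covers["future"],
        features=features,
        feature_cv=cvs,
        lek_abundance=lek_ab,
        lek_abundance_cv=lek_ab_cv,
        soil_moisture=soil,
        soil_moisture_cv=soil_cv,
        cluster_zones=clusters,
        conservation_areas=areas,
        leks=leks,
        seed=seed,
        config=cfg,
    )


def write_bundle(bundle: LandscapeBundle, outdir) -> None:
    """Write a bundle to a directory as GeoTIFF + GeoJSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rasters = {
        "historic_cover": bundle.historic_cover,
        "potential_cover": bundle.potential_cover,
        "current_cover": bundle.current_cover,
        "future_cover": bundle.future_cover,
        "soil_moisture": bundle.soil_moisture,
        "soil_moisture_cv": bundle.soil_moisture_cv,
        "lek_abundance": bundle.lek_abundance,
        "lek_abundance_cv": bundle.lek_abundance_cv,
    }
    for name, grid in bundle.features.items():
        rasters[f"feature_{name}"] = grid
    for name, grid in bundle.feature_cv.items():
        rasters[f"feature_{name}_cv"] = grid
    for name, grid in rasters.items():
        write_raster(grid, out / f"{name}.tif")
    write_polygons(bundle.cluster_zones, out / "cluster_zones.geojson")
    write_polygons(bundle.conservation_areas, out / "conservation_areas.geojson")
    write_points(bundle.leks, out / "leks.geojson")
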