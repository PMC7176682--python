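"""Synthetic landscape bundles.

Downstream stages (human-modification surface, resistance, circuit
solves) only assume a particular *structure* of inputs: a stack of
binary footprint occupancy layers, a two-region mask separating a
forest-dominated from an agriculture-dominated area, a percent-slope
field, a water mask, and a study-area mask sitting inside a buffered
extent.  This module generates bundles with that structure so every
stage is testable end-to-end without any external dataset.

The generator emulates the salient spatial features of a real human
footprint inventory: spatially autocorrelated patches (thresholded
smoothed noise), at least one category rendered as one-cell-wide
polylines (the roads/railways analogue, whose rasterization artefacts
matter for connectivity), contiguous water patches, and a smooth
non-negative slope field.  It does not emulate land-cover semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import Raster

__all__ = [
    "LandscapeConfig",
    "LandscapeBundle",
    "generate_landscape",
    "generate_catalog",
    "REGION_FOREST",
    "REGION_AGRICULTURE",
    "REGIONS",
]

# region mask codes
REGION_FOREST = 0.0
REGION_AGRICULTURE = 1.0
REGIONS = ("forest", "agriculture")


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of a synthetic landscape.

    ``study_height``/``study_width`` give the study-area size in fine
    cells; the full grid adds a buffer ring of width
    ``buffer_fraction * study_width`` on every side.  A buffer of at
    least 20% of the study-area width is required — narrower buffers
    are known to leave node-placement bias in the current maps.
    """

    study_height: int = 180
    study_width: int = 180
    cell_size: float = 10.0
    buffer_fraction: float = 1.0 / 3.0
    n_categories: int = 6
    coverage: float = 0.05          # expected per-category cover fraction
    water_fraction: float = 0.05
    slope_smoothness: float = 8.0   # gaussian sigma, in cells
    max_slope: float = 40.0         # percent slope at the steepest cell
    overlap: float = 0.3            # 0 = independent categories, 1 = co-located
    seed: int = 0

    def __post_init__(self) -> None:
        if self.study_height < 4 or self.study_width < 4:
            raise ValueError("study area must be at least 4x4 cells")
        if self.buffer_fraction < 0.2:
            raise ValueError("buffer_fraction must be >= 0.2 of the study width")
        if self.n_categories < 0:
            raise ValueError("n_categories must be >= 0")
        for name in ("coverage", "water_fraction", "overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.max_slope <= 100.0:
            raise ValueError("max_slope must lie in [0, 100]")

    @property
    def buffer_cells(self) -> int:
        return math.ceil(self.buffer_fraction * self.study_width)

    @property
    def grid_shape(self) -> tuple[int, int]:
        b = self.buffer_cells
        return (self.study_height + 2 * b, self.study_width + 2 * b)


@dataclass
class LandscapeBundle:
    """All rasters of one synthetic landscape, on a shared grid."""

    footprints: list[Raster]
    region: Raster        # REGION_FOREST / REGION_AGRICULTURE codes
    slope: Raster         # percent slope in [0, 100]
    water: Raster         # {0, 1}
    study_mask: Raster    # 1 inside the study area, 0 in the buffer ring
    config: LandscapeConfig | None = None

    def __post_init__(self) -> None:
        ref = self.region
        for r in [*self.footprints, self.slope, self.water, self.study_mask]:
            if not ref.same_geometry(r):
                raise ValueError("all bundle rasters must share one geometry")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized gaussian-smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=max(sigma, 1e-6))
    return (f - f.mean()) / (f.std() or 1.0)


def _threshold_at_coverage(f: np.ndarray, fraction: float) -> np.ndarray:
    """Binary mask covering ~`fraction` of cells (top quantile of f)."""
    if fraction <= 0:
        return np.zeros_like(f)
    if fraction >= 1:
        return np.ones_like(f)
    cut = np.quantile(f, 1.0 - fraction)
    return (f > cut).astype(np.float64)


def _polyline_layer(rng: np.random.Generator, shape: tuple[int, int], n_lines: int) -> np.ndarray:
    """One-cell-wide polylines crossing the grid (roads analogue)."""
    layer = np.zeros(shape)
    h, w = shape
    for _ in range(n_lines):
        # endpoints on opposite grid edges so lines span the landscape
        if rng.random() < 0.5:
            r0, r1 = 0, h - 1
            c0, c1 = rng.integers(0, w, size=2)
        else:
            c0, c1 = 0, w - 1
            r0, r1 = rng.integers(0, h, size=2)
        n = 2 * max(abs(r1 - r0), abs(c1 - c0)) + 1
        rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, h - 1)
        cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, w - 1)
        layer[rr, cc] = 1.0
    return layer


def generate_landscape(config: LandscapeConfig) -> LandscapeBundle:
    """Generate a deterministic synthetic landscape from a config.

    The last footprint category is always rendered as one-cell-wide
    polylines; the remaining categories are autocorrelated patches.
    With ``overlap > 0`` patch categories share a common underlying
    field and therefore tend to co-occur.
    """
    rng = np.random.default_rng(config.seed)
    shape = config.grid_shape
    geom = dict(cell_size=config.cell_size, origin=(0.0, 0.0))

    # two-region mask: wavy horizontal boundary, forest to the north
    boundary = shape[0] / 2.0 + _smooth_field(rng, (1, shape[1]), config.slope_smoothness)[0] * shape[0] * 0.08
    rows = np.arange(shape[0])[:, None]
    region = np.where(rows < boundary[None, :], REGION_FOREST, REGION_AGRICULTURE).astype(np.float64)

    # footprint layers
    shared = _smooth_field(rng, shape, sigma=4.0)
    footprints: list[Raster] = []
    for k in range(config.n_categories):
        if k == config.n_categories - 1 and config.n_categories >= 1:
            layer = _polyline_layer(rng, shape, n_lines=3)
        else:
            own = _smooth_field(rng, shape, sigma=4.0)
            f = (1.0 - config.overlap) * own + config.overlap * shared
            layer = _threshold_at_coverage(f, config.coverage)
        footprints.append(Raster(layer, **geom))

    water = Raster(_threshold_at_coverage(_smooth_field(rng, shape, sigma=5.0),
                                          config.water_fraction), **geom)

    s = _smooth_field(rng, shape, sigma=config.slope_smoothness)
    s = (s - s.min()) / ((s.max() - s.min()) or 1.0) * config.max_slope
    slope = Raster(s, **geom)

    mask = np.zeros(shape)
    b = config.buffer_cells
    mask[b:b + config.study_height, b:b + config.study_width] = 1.0
    study_mask = Raster(mask, **geom)

    return LandscapeBundle(footprints=footprints, region=Raster(region, **geom),
                           slope=slope, water=water, study_mask=study_mask,
                           config=config)


def generate_catalog(n_categories: int, seed: int = 0):
    """Random footprint catalog: per category and region, h_F and h_U in [0, 1].

    Values are drawn independently for the forest- and agriculture-
    dominated regions, since the degree of modification attributed to
    the same footprint type may differ between them.
    """
    from .modification import FootprintCatalog

    if n_categories < 0:
        raise ValueError("n_categories must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_categories):
        for region in REGIONS:
            h_f, h_u = rng.uniform(0.0, 1.0, size=2)
            rows.append({"category": f"cat{k:02d}", "region": region,
                         "h_F": h_f, "h_U": h_u})
    table = pd.DataFrame(rows, columns=["category", "region", "h_F", "h_U"])
    return FootprintCatalog(table)
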