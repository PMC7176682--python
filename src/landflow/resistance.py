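"""Resistance surfaces from human modification, slope, and water.

A cell's resistance to movement is

    R = f(H) + s/4 + w_res * w

where f is a monotone scaling of the human-modification index H in
[0, 1], s is percent slope (a slope of 100% adds 100/4 = 25), and w is
the water flag with an additive penalty w_res.  Two scalings are
supported:

* high contrast: f(H) = (H + 1)^10  (f(1) = 1024, f(0.5) ~ 57.7)
* low contrast:  f(H) = 1 + 1000 H  (f(1) = 1001, f(0.5) = 501)

Both satisfy f(0) = 1, so natural cells have unit resistance and the
technical maximum of a fully modified water cell under the high
contrast scaling with w_res = 1000 is 2024.  The main-map water
penalty is (1.5)^10 = 57.665, the resistance an intermediate
modification of H = 0.5 would carry (printed elsewhere as 57.7); the
uncertainty analysis varies w_res over {0, 1000}.

Resistance is computed at fine resolution and then aggregated to the
analysis resolution by block means, mirroring the 10 m -> 100 m mean
aggregation of the original workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import Raster, require_aligned

__all__ = [
    "ScalingSpec",
    "ResistanceRaster",
    "WATER_RESISTANCE_MAIN",
    "WATER_RESISTANCE_LEVELS",
    "scale_modification",
    "resistance",
    "resistance_map",
    "aggregate",
]

#: additive water penalty of the main map: (0.5 + 1)^10
WATER_RESISTANCE_MAIN: float = 1.5 ** 10
#: low/high water-penalty levels of the factorial uncertainty design
WATER_RESISTANCE_LEVELS: dict[str, float] = {"low": 0.0, "high": 1000.0}

SLOPE_DIVISOR = 4.0


@dataclass(frozen=True)
class ScalingSpec:
    """Choice of the H -> f(H) scaling (``high`` or ``low`` contrast)."""

    contrast: str = "high"

    def __post_init__(self) -> None:
        if self.contrast not in ("high", "low"):
            raise ValueError("contrast must be 'high' or 'low'")

    def __call__(self, H):
        return scale_modification(H, self.contrast)


def scale_modification(H, contrast: str = "high"):
    """Apply the chosen scaling function to H (scalar or array)."""
    H = np.asarray(H, dtype=float)
    finite = H[np.isfinite(H)]
    if finite.size and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError("H must lie in [0, 1]")
    if contrast == "high":
        out = (H + 1.0) ** 10
    elif contrast == "low":
        out = 1.0 + H * 1000.0
    else:
        raise ValueError("contrast must be 'high' or 'low'")
    return out if out.ndim else float(out)


def resistance(H: float, s: float, w: int, scaling: ScalingSpec | str = "high",
               w_res: float = WATER_RESISTANCE_MAIN) -> float:
    """Resistance of a single cell: f(H) + s/4 + w_res * w."""
    contrast = scaling.contrast if isinstance(scaling, ScalingSpec) else scaling
    if not 0.0 <= s <= 100.0:
        raise ValueError("percent slope must lie in [0, 100]")
    if w not in (0, 1):
        raise ValueError("water flag must be 0 or 1")
    if w_res < 0:
        raise ValueError("water resistance must be >= 0")
    return float(scale_modification(H, contrast) + s / SLOPE_DIVISOR + w_res * w)


@dataclass
class ResistanceRaster:
    """Resistance raster (R >= 1 everywhere) with its provenance."""

    raster: Raster
    provenance: dict = field(default_factory=dict)
    resolution: str = "fine"

    def __post_init__(self) -> None:
        d = self.raster.data
        finite = d[np.isfinite(d)]
        if finite.size and finite.min() < 1.0 - 1e-9:
            raise ValueError("resistance must be >= 1 everywhere")


def resistance_map(msurf, bundle, scaling: ScalingSpec | str = "high",
                   w_res: float = WATER_RESISTANCE_MAIN) -> ResistanceRaster:
    """Cell-wise resistance from an H surface plus slope and water rasters.

    Water cells keep their footprint-derived f(H) term; the water
    penalty is purely additive on top of it.
    """
    contrast = scaling.contrast if isinstance(scaling, ScalingSpec) else scaling
    H = msurf.raster
    require_aligned(H, bundle.slope, bundle.water)
    s = bundle.slope.data
    finite_s = s[np.isfinite(s)]
    if finite_s.size and ((finite_s < 0).any() or (finite_s > 100).any()):
        raise ValueError("percent slope must lie in [0, 100]")
    w = bundle.water.data
    R = scale_modification(H.data, contrast) + s / SLOPE_DIVISOR + w_res * w
    prov = {"index": msurf.index, "contrast": contrast,
            "water_resistance": float(w_res), "slope_divisor": SLOPE_DIVISOR}
    return ResistanceRaster(raster=H.copy_with(R), provenance=prov, resolution="fine")


def _block_reduce_mean(data: np.ndarray, factor: int) -> np.ndarray:
    """NaN-aware block mean; trailing partial blocks average available cells."""
    h, w = data.shape
    H = -(-h // factor) * factor
    W = -(-w // factor) * factor
    padded = np.full((H, W), np.nan)
    padded[:h, :w] = data
    blocks = padded.reshape(H // factor, factor, W // factor, factor)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(blocks, axis=(1, 3))
    return out


def aggregate(r: ResistanceRaster, factor: int) -> ResistanceRaster:
    """Aggregate to coarser resolution by the mean of factor x factor blocks.

    A coarse cell is NoData only when all its contributing fine cells
    are NoData.  When the factor divides the grid exactly, the global
    mean is conserved.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    if factor == 1:
        return ResistanceRaster(raster=r.raster, provenance=dict(r.provenance),
                                resolution=r.resolution)
    coarse = _block_reduce_mean(r.raster.data, factor)
    out = Raster(coarse, cell_size=r.raster.cell_size * factor,
                 origin=r.raster.origin)
    prov = dict(r.provenance)
    prov["aggregation_factor"] = int(factor)
    return ResistanceRaster(raster=out, provenance=prov, resolution="aggregated")


def aggregate_mask(mask: Raster, factor: int, threshold: float = 0.5) -> Raster:
    """Coarsen a {0,1} mask: coarse cell is 1 when the block mean >= threshold."""
    if factor == 1:
        return mask
    frac = _block_reduce_mean(mask.data, factor)
    out = np.where(np.isfinite(frac), (frac >= threshold).astype(float), np.nan)
    return Raster(out, cell_size=mask.cell_size * factor, origin=mask.origin)
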