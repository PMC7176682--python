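"""Degree-of-human-modification surfaces.

Each footprint category j carries an expert-style degree of
modification h_j in [0, 1], split into a physical-footprint value
(h_F) and an intensity-of-use value (h_U), possibly differing between
the forest- and agriculture-dominated regions.  Per cell, the h values
of all categories present are combined with the fuzzy algebraic sum

    H = 1 - prod_j (1 - h_j)

which is at least as large as its largest term, additive in effect,
and never exceeds 1.  A cell with no footprint has H = 0.

Three index variants are supported: ``H_F`` (physical footprint only),
``H_U`` (use intensity only), and ``H_FU`` (their mean).  By default
the averaging for H_FU happens at the per-category h level, before the
fuzzy sum; averaging the finished H_F and H_U surfaces instead is
available via ``fu_mode="surface"`` (the two agree exactly wherever at
most one footprint is present).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Raster, require_aligned

__all__ = [
    "FootprintCatalog",
    "ModificationSurface",
    "INDEX_CHOICES",
    "effective_h",
    "fuzzy_sum",
    "modification_surface",
]

INDEX_CHOICES = ("H_F", "H_U", "H_FU")


class FootprintCatalog:
    """Mapping (category, region) -> (h_F, h_U), both in [0, 1]."""

    def __init__(self, table: pd.DataFrame):
        required = {"category", "region", "h_F", "h_U"}
        if not required.issubset(table.columns):
            raise ValueError(f"catalog needs columns {sorted(required)}")
        vals = table[["h_F", "h_U"]].to_numpy(dtype=float)
        if vals.size and ((vals < 0).any() or (vals > 1).any()):
            raise ValueError("catalog h values must lie in [0, 1]")
        self._table = table.reset_index(drop=True)
        self._index = {
            (r.category, r.region): (float(r.h_F), float(r.h_U))
            for r in table.itertuples()
        }
        by_cat: dict[str, set[str]] = {}
        for cat, region in self._index:
            by_cat.setdefault(cat, set()).add(region)
        regions = set(table["region"])
        for cat, have in by_cat.items():
            if have != regions:
                raise ValueError(f"category {cat!r} missing a region entry")

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def categories(self) -> list[str]:
        seen: dict[str, None] = {}
        for cat in self._table["category"]:
            seen.setdefault(cat, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.categories)

    def lookup(self, category: str, region: str) -> tuple[float, float]:
        try:
            return self._index[(category, region)]
        except KeyError:
            raise KeyError(f"no catalog entry for ({category!r}, {region!r})") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "FootprintCatalog":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self._table.to_csv(path, index=False)


@dataclass
class ModificationSurface:
    """Raster of H in [0, 1] for one index choice."""

    raster: Raster
    index: str

    def __post_init__(self) -> None:
        if self.index not in INDEX_CHOICES:
            raise ValueError(f"index must be one of {INDEX_CHOICES}")
        d = self.raster.data
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("H values must lie in [0, 1]")


def effective_h(catalog: FootprintCatalog, category: str, region: str,
                index: str) -> float:
    """h value for one category/region under an index choice.

    H_F and H_U select the respective column; H_FU is the arithmetic
    mean (h_F + h_U) / 2.
    """
    h_f, h_u = catalog.lookup(category, region)
    if index == "H_F":
        return h_f
    if index == "H_U":
        return h_u
    if index == "H_FU":
        return (h_f + h_u) / 2.0
    raise ValueError(f"index must be one of {INDEX_CHOICES}")


def fuzzy_sum(h_values) -> float:
    """Fuzzy algebraic sum 1 - prod(1 - h) of values in [0, 1].

    The empty combination returns 0 (no footprint).  The result is
    bounded below by max(h) and above by min(1, sum(h)); 1 is
    absorbing.
    """
    h = np.asarray(list(h_values), dtype=float)
    if h.size == 0:
        return 0.0
    if (h < 0).any() or (h > 1).any():
        raise ValueError("fuzzy_sum inputs must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - h))


def _h_grid(bundle, catalog: FootprintCatalog, category: str, index: str) -> np.ndarray:
    """Per-cell h for one category, chosen by the cell's region."""
    from .synthetic import REGION_AGRICULTURE, REGIONS

    values = {region: effective_h(catalog, category, region, index) for region in REGIONS}
    agri = bundle.region.data == REGION_AGRICULTURE
    return np.where(agri, values["agriculture"], values["forest"])


def modification_surface(bundle, catalog: FootprintCatalog, index: str = "H_FU",
                         fu_mode: str = "per_category") -> ModificationSurface:
    """Combine all footprint layers of a bundle into an H surface.

    Per cell, every category whose occupancy layer is 1 contributes its
    region-specific h under the chosen index; contributions combine via
    the fuzzy algebraic sum.  ``fu_mode`` selects whether the H_FU mean
    is taken per category before the fuzzy sum (default) or on the
    finished H_F and H_U surfaces.
    """
    if index not in INDEX_CHOICES:
        raise ValueError(f"index must be one of {INDEX_CHOICES}")
    if fu_mode not in ("per_category", "surface"):
        raise ValueError("fu_mode must be 'per_category' or 'surface'")
    if index == "H_FU" and fu_mode == "surface":
        hf = modification_surface(bundle, catalog, "H_F").raster.data
        hu = modification_surface(bundle, catalog, "H_U").raster.data
        out = bundle.region.copy_with((hf + hu) / 2.0)
        return ModificationSurface(raster=out, index="H_FU")

    cats = catalog.categories
    if len(bundle.footprints) != len(cats):
        raise ValueError(
            f"bundle has {len(bundle.footprints)} footprint layers but the "
            f"catalog lists {len(cats)} categories"
        )
    require_aligned(bundle.region, *bundle.footprints)

    complement = np.ones(bundle.region.shape)
    for layer, cat in zip(bundle.footprints, cats):
        occ = layer.data
        if not np.isin(occ[np.isfinite(occ)], (0.0, 1.0)).all():
            raise ValueError(f"footprint layer {cat!r} is not binary")
        h = _h_grid(bundle, catalog, cat, index)
        complement *= 1.0 - h * occ
    H = 1.0 - complement
    return ModificationSurface(raster=bundle.region.copy_with(np.clip(H, 0.0, 1.0)),
                               index=index)
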