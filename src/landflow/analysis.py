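"""Map standardization, comparison, and variance partitioning.

Current-density maps from different parameterizations live on
different absolute scales, so comparison starts from z-scores
(z = (x - mean)/sd over the valid, clipped cells).  Cells with z above
a cutoff (0, 1, or 2) are classified as important contributors to
connectivity.  An ensemble of maps from a full 2x2x2 factorial design
(H index x water resistance x scaling function) is compared through a
Pearson correlation matrix and per-cutoff agreement matrices; these
are converted to dissimilarities and the between-map variation is
partitioned among the three design factors with distance-based
redundancy analysis (db-RDA): principal coordinates of the
Gower-centred -D^2/2 matrix, redundancy analysis on dummy-coded
factors, Ezekiel-adjusted R^2, and unique (marginal) fractions by
inclusion-exclusion — the same decomposition vegan's ``varpart``
performs.

A note on the dissimilarity scale: for z-standardized maps the
cell-space Euclidean distance between two maps is exactly
sqrt(2 n (1 - r)), so running db-RDA on the *square root* of 1 - r
(``sqrt_distances=True``, the analogue of vegan's ``sqrt.dist``)
makes the ordination geometry identical to a classical RDA on the
maps themselves and keeps all eigenvalues non-negative.  Using 1 - r
directly is also supported but embeds with negative eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd

from .grids import Raster
from .circuit import CurrentDensityMap

__all__ = [
    "StandardizedMap",
    "FactorialDesign",
    "VariancePartition",
    "ComparisonResult",
    "standardize",
    "classify",
    "correlation_matrix",
    "agreement_matrix",
    "to_dissimilarity",
    "varpart_dbrda",
    "load_reference_correlations",
    "reanalyze_reference",
    "run_uncertainty_analysis",
]

FACTORS = ("water", "scaling", "h_index")


# ---------------------------------------------------------------------------
# standardization and classification

@dataclass
class StandardizedMap:
    """z-scored current density; mean 0 and sd 1 over valid cells."""

    raster: Raster
    provenance: dict = field(default_factory=dict)


def standardize(cdm: CurrentDensityMap | Raster) -> StandardizedMap:
    """z = (x - mean)/sd over valid cells (population sd); NoData kept."""
    raster = cdm.raster if isinstance(cdm, CurrentDensityMap) else cdm
    data = raster.data
    valid = np.isfinite(data)
    if valid.sum() < 2:
        raise ValueError("need at least two valid cells to standardize")
    mean = data[valid].mean()
    sd = data[valid].std()  # population convention (ddof=0)
    if sd == 0:
        raise ValueError("cannot standardize a constant map (zero variance)")
    prov = dict(getattr(cdm, "meta", {}))
    return StandardizedMap(raster=raster.copy_with((data - mean) / sd),
                           provenance=prov)


def classify(z: StandardizedMap, cutoff: float) -> Raster:
    """Binary importance raster: 1 where z >= cutoff (ties inclusive)."""
    data = z.raster.data
    out = np.where(np.isfinite(data), (data >= cutoff).astype(float), np.nan)
    return z.raster.copy_with(out)


# ---------------------------------------------------------------------------
# pairwise map comparison

def _stack_valid(rasters: list[Raster]) -> np.ndarray:
    ref_mask = rasters[0].valid
    for r in rasters[1:]:
        if r.data.shape != rasters[0].data.shape or not np.array_equal(r.valid, ref_mask):
            raise ValueError("maps must share shape and valid-cell mask")
    return np.stack([r.data[ref_mask] for r in rasters])


def correlation_matrix(maps: list[StandardizedMap | Raster]) -> np.ndarray:
    """Cell-by-cell Pearson correlation between every pair of maps."""
    rasters = [m.raster if isinstance(m, StandardizedMap) else m for m in maps]
    X = _stack_valid(rasters)
    r = np.corrcoef(X)
    np.fill_diagonal(r, 1.0)
    return r


def agreement_matrix(classified: list[Raster]) -> np.ndarray:
    """Proportion of valid cells classified identically, per map pair."""
    X = _stack_valid(classified)
    n_maps, n_cells = X.shape
    out = np.ones((n_maps, n_maps))
    for i, j in combinations(range(n_maps), 2):
        out[i, j] = out[j, i] = np.mean(X[i] == X[j])
    return out


def to_dissimilarity(m: np.ndarray, transform: str = "one_minus") -> np.ndarray:
    """Convert a similarity/correlation matrix to dissimilarities.

    ``one_minus`` gives D = 1 - m (default); ``sqrt`` gives
    sqrt(1 - m), the metric embedding for correlation similarities.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("matrix must be symmetric")
    if (m > 1 + 1e-12).any():
        raise ValueError("similarity entries must be <= 1")
    if not np.allclose(np.diag(m), 1.0):
        raise ValueError("similarity diagonal must be 1")
    D = 1.0 - m
    if transform == "sqrt":
        D = np.sqrt(np.clip(D, 0.0, None))
    elif transform != "one_minus":
        raise ValueError("transform must be 'one_minus' or 'sqrt'")
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# factorial design

@dataclass(frozen=True)
class FactorialDesign:
    """Full 2x2x2 design over water resistance, scaling, and H index.

    Dummy coding: water high = 1 / low = 0; scaling high contrast = 1 /
    low = 0; H index H_F = 1 / H_U = 0.  The main (H_FU, intermediate
    water) map sits outside the factorial.
    """

    levels: tuple = ()

    @classmethod
    def default(cls) -> "FactorialDesign":
        combos = []
        for scaling in ("high", "low"):
            for water in ("high", "low"):
                for h_index in ("H_F", "H_U"):
                    combos.append({"scaling": scaling, "water": water,
                                   "h_index": h_index})
        return cls(levels=tuple(tuple(sorted(c.items())) for c in combos))

    @property
    def rows(self) -> list[dict]:
        return [dict(lv) for lv in self.levels]

    @property
    def labels(self) -> list[str]:
        return [
            f"scale{r['scaling']}.water{r['water']}.{r['h_index'].replace('_', '')}"
            for r in self.rows
        ]

    def dummies(self) -> dict[str, np.ndarray]:
        rows = self.rows
        return {
            "water": np.array([1.0 if r["water"] == "high" else 0.0 for r in rows]),
            "scaling": np.array([1.0 if r["scaling"] == "high" else 0.0 for r in rows]),
            "h_index": np.array([1.0 if r["h_index"] == "H_F" else 0.0 for r in rows]),
        }

    def __len__(self) -> int:
        return len(self.levels)


# ---------------------------------------------------------------------------
# db-RDA variance partitioning

@dataclass
class VariancePartition:
    """Unique adjusted fractions per factor plus the unexplained rest (%)."""

    unique: dict[str, float]
    unexplained: float
    full_model: float
    adjusted: bool = True
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "fraction_pct": v} for k, v in self.unique.items()]
        rows.append({"component": "unexplained", "fraction_pct": self.unexplained})
        return pd.DataFrame(rows)


def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    A = -0.5 * D ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _lingoes(D: np.ndarray) -> np.ndarray:
    w = np.linalg.eigvalsh(_gower_center(D))
    c = max(0.0, -w.min())
    if c == 0.0:
        return D
    out = np.sqrt(D ** 2 + 2.0 * c)
    np.fill_diagonal(out, 0.0)
    return out


def _cailliez(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    delta1 = J @ (-0.5 * D ** 2) @ J
    delta2 = J @ (-0.5 * D) @ J
    Z = np.zeros((2 * n, 2 * n))
    Z[:n, n:] = 2.0 * delta1
    Z[n:, :n] = -np.eye(n)
    Z[n:, n:] = -4.0 * delta2
    c = max(0.0, float(np.real(np.linalg.eigvals(Z)).max()))
    if c == 0.0:
        return D
    out = D + c
    np.fill_diagonal(out, 0.0)
    return out


def _pcoa_coordinates(D: np.ndarray) -> tuple[np.ndarray, float]:
    """Positive-eigenvalue principal coordinates and total kept inertia."""
    G = _gower_center(D)
    w, V = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = 1e-10 * max(1.0, abs(w).max())
    keep = w > tol
    return V[:, keep] * np.sqrt(w[keep]), float(w[keep].sum())


def _rda_r2(Y: np.ndarray, X: np.ndarray, total: float) -> float:
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    return float(np.sum((Xc @ beta) ** 2) / total)


def varpart_dbrda(D: np.ndarray, design: FactorialDesign | dict[str, np.ndarray],
                  adjusted: bool = True, sqrt_distances: bool = False,
                  correction: str | None = None) -> VariancePartition:
    """Partition a dissimilarity matrix among dummy-coded factors.

    Steps: optional sqrt/Lingoes/Cailliez treatment of the distances;
    principal coordinates of the Gower-centred -D^2/2 (axes with
    positive eigenvalues retained); RDA R^2 of the coordinates on every
    non-empty factor subset; Ezekiel adjustment
    R^2_adj = 1 - (1 - R^2)(n-1)/(n-p-1); unique (marginal) fraction of
    each factor = full-model R^2_adj minus the R^2_adj of the other
    factors; unexplained = 100% minus the sum of unique fractions.
    Negative adjusted fractions are reported as-is.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-10) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("D must be symmetric with a zero diagonal")
    if (D < -1e-12).any():
        raise ValueError("dissimilarities must be non-negative")

    X = design.dummies() if isinstance(design, FactorialDesign) else dict(design)
    names = list(X)
    for nm, col in X.items():
        if len(col) != n:
            raise ValueError(f"factor {nm!r} length does not match D")
    M = np.column_stack([X[nm] for nm in names])
    if np.linalg.matrix_rank(M - M.mean(axis=0)) < M.shape[1]:
        raise ValueError("design dummies are collinear")

    if sqrt_distances:
        D = np.sqrt(D)
    if correction == "lingoes":
        D = _lingoes(D)
    elif correction == "cailliez":
        D = _cailliez(D)
    elif correction is not None:
        raise ValueError("correction must be None, 'lingoes', or 'cailliez'")

    Y, total = _pcoa_coordinates(D)
    if total <= 0 or Y.shape[1] == 0:
        return VariancePartition(unique={nm: 0.0 for nm in names},
                                 unexplained=100.0, full_model=0.0,
                                 adjusted=adjusted, degenerate=True)

    def fit(subset: tuple[str, ...]) -> float:
        r2 = _rda_r2(Y, np.column_stack([X[nm] for nm in subset]), total)
        if adjusted:
            p = len(subset)
            r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        return r2

    r2_by_subset = {sub: fit(sub) for k in range(1, len(names) + 1)
                    for sub in combinations(names, k)}
    full = r2_by_subset[tuple(names)]
    unique = {nm: 100.0 * (full - r2_by_subset[tuple(o for o in names if o != nm)])
              for nm in names}
    unexplained = 100.0 - sum(unique.values())
    return VariancePartition(unique=unique, unexplained=unexplained,
                             full_model=100.0 * full, adjusted=adjusted)


# ---------------------------------------------------------------------------
# packaged reference matrix and its reanalysis

def load_reference_correlations() -> pd.DataFrame:
    """The published 8x8 Pearson correlation matrix between the eight
    Alberta current-density maps of the factorial uncertainty design,
    labelled by factor levels (scaling.water.index)."""
    with resources.files("landflow.data").joinpath(
            "alberta_map_correlations.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    df.index.name = "map"
    return df


def reanalyze_reference(transform: str = "one_minus",
                        sqrt_distances: bool = True,
                        adjusted: bool = True) -> VariancePartition:
    """db-RDA variance partitioning of the packaged correlation matrix.

    Defaults follow the metric route (square-rooted 1 - r distances,
    adjusted R^2), under which the ordination is exactly the geometry
    of the z-standardized maps.
    """
    corr = load_reference_correlations()
    design = FactorialDesign.default()
    if list(corr.index) != design.labels:
        raise ValueError("fixture ordering does not match the factorial design")
    D = to_dissimilarity(corr.to_numpy(), transform=transform)
    return varpart_dbrda(D, design, adjusted=adjusted,
                         sqrt_distances=sqrt_distances)


# ---------------------------------------------------------------------------
# end-to-end factorial comparison

@dataclass
class SolverConfig:
    """Circuit-solver settings shared across an ensemble run."""

    n_nodes: int = 20
    threshold: float = 0.999
    neighbourhood: int = 8
    seed: int = 0
    min_pairs: int = 10
    batch: int = 1
    max_pairs: int | None = None


@dataclass
class ComparisonResult:
    """All ensemble comparison outputs for one landscape."""

    labels: list[str]
    correlation: pd.DataFrame
    agreement: dict[float, pd.DataFrame]
    dissimilarity: dict[str, pd.DataFrame]
    partitions: dict[str, VariancePartition]
    maps: dict[str, CurrentDensityMap]
    zmaps: dict[str, StandardizedMap]
    main_map: CurrentDensityMap | None = None
    main_z: StandardizedMap | None = None


def _single_map(bundle, catalog, index: str, scaling: str, w_res: float,
                solver: SolverConfig, aggregation_factor: int,
                pair_seed: int) -> CurrentDensityMap:
    from .modification import modification_surface
    from .resistance import resistance_map, aggregate, aggregate_mask
    from .circuit import (build_graph, place_boundary_nodes, accumulate,
                          clip_to_study_area)

    msurf = modification_surface(bundle, catalog, index)
    rmap = aggregate(resistance_map(msurf, bundle, scaling, w_res),
                     aggregation_factor)
    graph = build_graph(rmap, neighbourhood=solver.neighbourhood)
    nodes = place_boundary_nodes(graph, solver.n_nodes, seed=solver.seed)
    cdm = accumulate(graph, nodes, threshold=solver.threshold, seed=pair_seed,
                     min_pairs=solver.min_pairs, batch=solver.batch,
                     max_pairs=solver.max_pairs)
    mask = aggregate_mask(bundle.study_mask, aggregation_factor)
    return clip_to_study_area(cdm, mask)


def run_uncertainty_analysis(bundle, catalog,
                             design: FactorialDesign | None = None,
                             solver: SolverConfig | None = None,
                             aggregation_factor: int = 3,
                             cutoffs: tuple[float, ...] = (0.0, 1.0, 2.0),
                             transform: str = "one_minus",
                             sqrt_distances: bool = True,
                             include_main: bool = True) -> ComparisonResult:
    """Build the 8 factorial maps (plus the main H_FU map), compare them,
    and partition between-map variation among the design factors.

    Boundary-node locations are shared across maps (same seeded
    placement); the random pair sequence differs per map, as in
    independent solver runs.
    """
    from .resistance import WATER_RESISTANCE_LEVELS, WATER_RESISTANCE_MAIN

    design = design or FactorialDesign.default()
    solver = solver or SolverConfig()
    labels = design.labels

    seeds = np.random.SeedSequence(solver.seed).generate_state(len(design) + 1)
    seeds = [int(s % (2 ** 31)) for s in seeds]

    maps: dict[str, CurrentDensityMap] = {}
    for k, row in enumerate(design.rows):
        maps[labels[k]] = _single_map(
            bundle, catalog, row["h_index"], row["scaling"],
            WATER_RESISTANCE_LEVELS[row["water"]], solver,
            aggregation_factor, pair_seed=seeds[k])

    zmaps = {lab: standardize(maps[lab]) for lab in labels}

    corr = correlation_matrix([zmaps[lab] for lab in labels])
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)

    agreement: dict[float, pd.DataFrame] = {}
    for cut in cutoffs:
        cls = [classify(zmaps[lab], cut) for lab in labels]
        agreement[cut] = pd.DataFrame(agreement_matrix(cls), index=labels,
                                      columns=labels)

    dissimilarity: dict[str, pd.DataFrame] = {}
    partitions: dict[str, VariancePartition] = {}
    matrices = {"correlation": corr_df}
    matrices.update({f"agreement_z{cut:g}": agreement[cut] for cut in cutoffs})
    for name, mat in matrices.items():
        D = to_dissimilarity(mat.to_numpy(), transform=transform)
        dissimilarity[name] = pd.DataFrame(D, index=labels, columns=labels)
        partitions[name] = varpart_dbrda(D, design,
                                         sqrt_distances=sqrt_distances)

    main_map = main_z = None
    if include_main:
        main_map = _single_map(bundle, catalog, "H_FU", "high",
                               WATER_RESISTANCE_MAIN, solver,
                               aggregation_factor, pair_seed=seeds[-1])
        main_z = standardize(main_map)

    return ComparisonResult(labels=labels, correlation=corr_df,
                            agreement=agreement, dissimilarity=dissimilarity,
                            partitions=partitions, maps=maps, zmaps=zmaps,
                            main_map=main_map, main_z=main_z)
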