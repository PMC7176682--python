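"""Circuit-theory current density on resistance rasters.

The raster is treated as a resistor network: each valid cell is a
node, neighbouring cells are joined by a resistor whose conductance is
the inverse of the mean of the two cell resistances (half-cell series
convention); diagonal neighbours (8-neighbourhood) are additionally
down-weighted by 1/sqrt(2) for the longer centre-to-centre distance.
Injecting one unit of current between a source and a sink cell and
solving the graph Laplacian system gives node voltages; per-cell
current density is half the sum of the absolute currents on incident
edges, with the two terminals set to the injected magnitude so that a
pass-through cell in a uniform chain registers exactly 1.

An omnidirectional map is accumulated by summing solves over node
pairs sampled uniformly at random (without replacement) from a set of
points spread evenly along the outer margin of the buffered extent;
accumulation stops once the Pearson correlation between successive
cumulative maps reaches a threshold (default 0.999).  The buffer ring
is clipped afterwards, which removes the node-placement bias from the
retained study area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .grids import Raster
from .resistance import ResistanceRaster

__all__ = [
    "ConductanceGraph",
    "NodeSet",
    "CurrentDensityMap",
    "build_graph",
    "place_boundary_nodes",
    "solve_pair",
    "effective_resistance",
    "accumulate",
    "clip_to_study_area",
]


@dataclass
class ConductanceGraph:
    """Sparse resistor network over the valid cells of a raster."""

    shape: tuple[int, int]
    cells: np.ndarray          # (n, 2) row/col of each node
    node_index: np.ndarray     # 2-D int array, -1 for invalid cells
    edges: np.ndarray          # (m, 2) node ids
    conductance: np.ndarray    # (m,)
    neighbourhood: int
    geometry: Raster           # carries cell size / origin of the source raster
    _lu: object | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return len(self.cells)

    def laplacian(self) -> sparse.csr_matrix:
        i, j = self.edges[:, 0], self.edges[:, 1]
        c = self.conductance
        n = self.n_nodes
        A = sparse.coo_matrix(
            (np.concatenate([c, c]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        ).tocsr()
        deg = np.asarray(A.sum(axis=1)).ravel()
        return sparse.diags(deg) - A

    def _factor(self):
        """LU factorization of the Laplacian grounded at node 0 (cached)."""
        if self._lu is None:
            L = self.laplacian().tocsc()
            self._lu = splu(L[1:, 1:])
        return self._lu

    def solve_voltages(self, source: int, sink: int) -> np.ndarray:
        """Node voltages for unit current source -> sink, ground at node 0.

        Per-cell currents are invariant to the grounding choice; only
        the additive voltage constant depends on it.
        """
        if source == sink:
            raise ValueError("source and sink must differ")
        n = self.n_nodes
        b = np.zeros(n)
        b[source] += 1.0
        b[sink] -= 1.0
        v = np.empty(n)
        v[0] = 0.0
        v[1:] = self._factor().solve(b[1:])
        return v

    def node_at(self, cell: tuple[int, int]) -> int:
        nid = int(self.node_index[cell])
        if nid < 0:
            raise KeyError(f"cell {cell} is not a graph node")
        return nid


def build_graph(r: ResistanceRaster | Raster, neighbourhood: int = 8,
                convention: str = "mean_resistance") -> ConductanceGraph:
    """Build the conductance graph of a resistance raster.

    ``convention`` selects the edge weight between neighbours with
    resistances R_i, R_j: ``mean_resistance`` (default) uses
    1 / ((R_i + R_j)/2); ``mean_conductance`` uses (1/R_i + 1/R_j)/2.
    Diagonal edges are divided by sqrt(2).  Raises if fewer than two
    valid cells remain or the graph is disconnected.
    """
    raster = r.raster if isinstance(r, ResistanceRaster) else r
    if neighbourhood not in (4, 8):
        raise ValueError("neighbourhood must be 4 or 8")
    if convention not in ("mean_resistance", "mean_conductance"):
        raise ValueError("unknown conductance convention")
    R = raster.data
    valid = np.isfinite(R)
    if valid.sum() < 2:
        raise ValueError("raster must contain at least two valid cells")
    if (R[valid] <= 0).any():
        raise ValueError("resistances must be positive")

    node_index = np.full(R.shape, -1, dtype=np.int64)
    cells = np.argwhere(valid)
    node_index[valid] = np.arange(len(cells))

    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbourhood == 8:
        offsets += [(1, 1, np.sqrt(2.0)), (1, -1, np.sqrt(2.0))]

    edges, conds = [], []
    h, w = R.shape
    for dr, dc, dist in offsets:
        r0 = slice(max(0, -dr), h - max(0, dr))
        c0 = slice(max(0, -dc), w - max(0, dc))
        r1 = slice(max(0, dr), h + min(0, dr) or h)
        c1 = slice(max(0, dc), w + min(0, dc) or w)
        a = node_index[r0, c0]
        b = node_index[r1, c1]
        Ra = R[r0, c0]
        Rb = R[r1, c1]
        ok = (a >= 0) & (b >= 0)
        if convention == "mean_resistance":
            c = 1.0 / ((Ra[ok] + Rb[ok]) / 2.0)
        else:
            c = (1.0 / Ra[ok] + 1.0 / Rb[ok]) / 2.0
        edges.append(np.column_stack([a[ok], b[ok]]))
        conds.append(c / dist)

    edge_arr = np.concatenate(edges)
    cond_arr = np.concatenate(conds)

    graph = ConductanceGraph(shape=R.shape, cells=cells, node_index=node_index,
                             edges=edge_arr, conductance=cond_arr,
                             neighbourhood=neighbourhood, geometry=raster)
    n = graph.n_nodes
    adj = sparse.coo_matrix((cond_arr, (edge_arr[:, 0], edge_arr[:, 1])), shape=(n, n))
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError(f"resistance raster is disconnected ({ncomp} components)")
    return graph


@dataclass
class NodeSet:
    """Ordered boundary nodes used as current terminals."""

    node_ids: list[int]
    cells: list[tuple[int, int]]
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.node_ids)


def _perimeter_cells(shape: tuple[int, int]) -> np.ndarray:
    """Cells of the outermost ring, clockwise from the top-left corner."""
    h, w = shape
    if h == 1:
        return np.array([(0, c) for c in range(w)])
    if w == 1:
        return np.array([(r, 0) for r in range(h)])
    ring = (
        [(0, c) for c in range(w)]
        + [(r, w - 1) for r in range(1, h)]
        + [(h - 1, c) for c in range(w - 2, -1, -1)]
        + [(r, 0) for r in range(h - 2, 0, -1)]
    )
    return np.array(ring)


def place_boundary_nodes(graph: ConductanceGraph, n: int, seed: int = 0) -> NodeSet:
    """Place n nodes at equal arc-length intervals along the outer margin.

    The starting position on the perimeter is a seeded random offset;
    each ideal position is snapped to the nearest valid (distinct)
    graph cell.
    """
    if n < 2:
        raise ValueError("need at least two boundary nodes")
    ring = _perimeter_cells(graph.shape)
    P = len(ring)
    if n > P:
        raise ValueError(f"{n} nodes exceed the {P} perimeter cells")
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, P)
    targets = ring[(np.round(offset + np.arange(n) * P / n).astype(int)) % P]

    tree = cKDTree(graph.cells)
    taken: set[int] = set()
    ids: list[int] = []
    cells: list[tuple[int, int]] = []
    for t in targets:
        k = 1
        while True:
            _, idx = tree.query(t, k=k)
            cand = np.atleast_1d(idx)[-1]
            if cand not in taken:
                break
            k += 1
        taken.add(int(cand))
        ids.append(int(cand))
        cells.append(tuple(int(x) for x in graph.cells[cand]))
    return NodeSet(node_ids=ids, cells=cells, seed=seed)


def _current_density(graph: ConductanceGraph, v: np.ndarray,
                     source: int, sink: int) -> np.ndarray:
    i, j = graph.edges[:, 0], graph.edges[:, 1]
    I = np.abs(graph.conductance * (v[i] - v[j]))
    acc = np.zeros(graph.n_nodes)
    np.add.at(acc, i, I)
    np.add.at(acc, j, I)
    dens = acc / 2.0
    dens[source] = 1.0
    dens[sink] = 1.0
    return dens


def solve_pair(graph: ConductanceGraph, source: int, sink: int) -> Raster:
    """Current-density raster for one unit-current source/sink pair."""
    v = graph.solve_voltages(source, sink)
    dens = _current_density(graph, v, source, sink)
    out = np.full(graph.shape, np.nan)
    out[tuple(graph.cells.T)] = dens
    return graph.geometry.copy_with(out)


def effective_resistance(graph: ConductanceGraph, source: int, sink: int) -> float:
    """Two-point effective resistance (voltage drop at unit current)."""
    v = graph.solve_voltages(source, sink)
    return float(v[source] - v[sink])


@dataclass
class CurrentDensityMap:
    """Accumulated current density with its convergence trace."""

    raster: Raster
    n_pairs: int
    trace: list[float] = field(default_factory=list)
    clipped: bool = False
    meta: dict = field(default_factory=dict)


def accumulate(graph: ConductanceGraph, nodes: NodeSet, threshold: float = 0.999,
               seed: int = 0, min_pairs: int = 10, batch: int = 1,
               max_pairs: int | None = None) -> CurrentDensityMap:
    """Sum pairwise solves over random node pairs until maps converge.

    Unordered pairs are drawn without replacement in a seeded random
    order.  Every ``batch`` solves (once ``min_pairs`` have been
    accumulated) the Pearson correlation between the previous and the
    current cumulative map is computed; accumulation stops when it
    reaches ``threshold``, when ``max_pairs`` is hit, or when all
    C(n, 2) pairs are spent.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    if min_pairs < 2:
        raise ValueError("min_pairs must be >= 2")
    rng = np.random.default_rng(seed)
    pairs = list(combinations(nodes.node_ids, 2))
    order = rng.permutation(len(pairs))
    if max_pairs is not None:
        order = order[:max_pairs]

    cumulative = np.zeros(graph.n_nodes)
    previous = cumulative.copy()
    trace: list[float] = []
    solved = 0
    for count, k in enumerate(order, start=1):
        s, t = pairs[k]
        v = graph.solve_voltages(s, t)
        cumulative += _current_density(graph, v, s, t)
        solved = count
        if count % batch == 0:
            if count >= min_pairs and previous.std() > 0:
                r = float(np.corrcoef(previous, cumulative)[0, 1])
                trace.append(r)
                if r >= threshold:
                    break
            previous = cumulative.copy()

    out = np.full(graph.shape, np.nan)
    out[tuple(graph.cells.T)] = cumulative
    return CurrentDensityMap(raster=graph.geometry.copy_with(out),
                             n_pairs=solved, trace=trace, clipped=False,
                             meta={"seed": seed, "threshold": threshold,
                                   "n_nodes": len(nodes)})


def clip_to_study_area(cdm: CurrentDensityMap, study_mask: Raster) -> CurrentDensityMap:
    """Drop buffer-only cells (mask 0 -> NoData); keeps geometry."""
    if not cdm.raster.same_geometry(study_mask):
        raise ValueError("study mask geometry does not match the map")
    data = np.where(study_mask.data == 1.0, cdm.raster.data, np.nan)
    return CurrentDensityMap(raster=cdm.raster.copy_with(data),
                             n_pairs=cdm.n_pairs, trace=list(cdm.trace),
                             clipped=True, meta=dict(cdm.meta))
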