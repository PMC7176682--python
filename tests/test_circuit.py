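import numpy as np
import pytest

from landflow import (Raster, build_graph, place_boundary_nodes, solve_pair,
                      effective_resistance, accumulate, clip_to_study_area)
from landflow.circuit import _current_density, _perimeter_cells


def dense_oracle_density(graph, source, sink):
    """Current density via the dense (symmetric) Laplacian pseudo-inverse."""
    from scipy.linalg import pinvh

    L = graph.laplacian().toarray()
    b = np.zeros(graph.n_nodes)
    b[source] += 1.0
    b[sink] -= 1.0
    v = pinvh(L) @ b
    return _current_density(graph, v, source, sink)


def grid_graph(data, neighbourhood=4):
    return build_graph(Raster(np.asarray(data, dtype=float)),
                       neighbourhood=neighbourhood)


def test_edge_conductance_conventions():
    g = grid_graph([[1.0, 3.0]])
    assert g.conductance[0] == pytest.approx(0.5)        # 1/mean(1,3)
    g4 = grid_graph(np.ones((3, 3)), neighbourhood=4)
    assert np.allclose(g4.conductance, 1.0)
    g8 = grid_graph(np.ones((2, 2)), neighbourhood=8)
    diag = np.sort(g8.conductance)[:2]                   # two diagonal edges
    assert np.allclose(diag, 1 / np.sqrt(2))


def test_mean_conductance_convention_option():
    g = build_graph(Raster(np.array([[1.0, 3.0]])), neighbourhood=4,
                    convention="mean_conductance")
    assert g.conductance[0] == pytest.approx((1 + 1 / 3) / 2)


def test_disconnected_raster_raises():
    data = np.array([[1.0, np.nan, 1.0]])
    with pytest.raises(ValueError, match="disconnected"):
        build_graph(Raster(data), neighbourhood=4)


def test_nonpositive_resistance_raises():
    with pytest.raises(ValueError):
        build_graph(Raster(np.array([[1.0, -2.0]])))


def test_uniform_chain_pass_through_current_is_one():
    g = grid_graph(np.ones((1, 5)))
    dens = solve_pair(g, g.node_at((0, 0)), g.node_at((0, 4))).data
    assert np.allclose(dens, 1.0)


def test_chain_effective_resistance_half_cell_convention():
    g = grid_graph([[1.0, 2.0, 1.0]])
    # inter-cell resistances mean(1,2) = 1.5 twice, in series
    assert effective_resistance(g, 0, 2) == pytest.approx(3.0, abs=1e-10)


def test_kirchhoff_conservation():
    rng = np.random.default_rng(3)
    g = grid_graph(1.0 + rng.random((6, 6)) * 9, neighbourhood=8)
    s, t = 0, g.n_nodes - 1
    v = g.solve_voltages(s, t)
    residual = g.laplacian() @ v
    b = np.zeros(g.n_nodes)
    b[s], b[t] = 1.0, -1.0
    assert np.abs(residual - b).max() < 1e-8


@pytest.mark.parametrize("seed", [7, 19, 101])
def test_sparse_solution_matches_dense_pseudoinverse(seed):
    rng = np.random.default_rng(seed)
    g = grid_graph(1.0 + rng.random((5, 5)) * 99, neighbourhood=8)
    s, t = 2, g.n_nodes - 3
    dens = solve_pair(g, s, t).data[np.isfinite(solve_pair(g, s, t).data)]
    oracle = dense_oracle_density(g, s, t)
    assert np.abs(dens - oracle).max() < 1e-8


def test_reciprocity_and_scale_invariance():
    rng = np.random.default_rng(11)
    R = 1.0 + rng.random((5, 5)) * 9
    g = grid_graph(R, neighbourhood=8)
    s, t = 1, g.n_nodes - 2
    a = solve_pair(g, s, t).data
    b = solve_pair(g, t, s).data
    assert np.nanmax(np.abs(a - b)) < 1e-10
    g10 = grid_graph(10.0 * R, neighbourhood=8)
    c = solve_pair(g10, s, t).data
    assert np.nanmax(np.abs(a - c)) < 1e-10


def test_barrier_raises_never_increases_through_current():
    base = np.ones((3, 3))
    g = grid_graph(base, neighbourhood=4)
    s, t = g.node_at((0, 0)), g.node_at((2, 2))
    before = solve_pair(g, s, t).data[1, 1]
    barrier = base.copy()
    barrier[1, 1] = 10.0
    g2 = grid_graph(barrier, neighbourhood=4)
    after = solve_pair(g2, g2.node_at((0, 0)), g2.node_at((2, 2))).data[1, 1]
    assert after <= before + 1e-12


def test_perimeter_ring_order_and_length():
    ring = _perimeter_cells((4, 5))
    assert len(ring) == 2 * (4 + 5) - 4
    assert tuple(ring[0]) == (0, 0)
    # consecutive ring cells are 8-adjacent
    d = np.abs(np.diff(ring, axis=0))
    assert d.max() == 1


def test_boundary_nodes_even_spacing(uniform_raster):
    g = build_graph(uniform_raster)
    nodes = place_boundary_nodes(g, 4, seed=0)
    ring = [tuple(c) for c in _perimeter_cells(g.shape)]
    pos = sorted(ring.index(c) for c in nodes.cells)
    gaps = np.diff(pos + [pos[0] + len(ring)])
    assert np.all(np.abs(gaps - len(ring) / 4) <= 2)

    two = place_boundary_nodes(g, 2, seed=5)
    p = sorted(ring.index(c) for c in two.cells)
    gap = min(p[1] - p[0], len(ring) - (p[1] - p[0]))
    assert gap >= 0.4 * len(ring)


def test_boundary_nodes_distinct_and_deterministic(uniform_raster):
    g = build_graph(uniform_raster)
    a = place_boundary_nodes(g, 10, seed=3)
    b = place_boundary_nodes(g, 10, seed=3)
    assert a.node_ids == b.node_ids
    assert len(set(a.node_ids)) == 10
    with pytest.raises(ValueError):
        place_boundary_nodes(g, 1)


def test_accumulate_two_nodes_is_single_solve(uniform_raster):
    g = build_graph(uniform_raster)
    nodes = place_boundary_nodes(g, 2, seed=0)
    cdm = accumulate(g, nodes, seed=1)
    assert cdm.n_pairs == 1
    single = solve_pair(g, nodes.node_ids[0], nodes.node_ids[1])
    assert np.allclose(cdm.raster.data, single.data, equal_nan=True)


def test_accumulate_deterministic(uniform_raster):
    g = build_graph(uniform_raster)
    nodes = place_boundary_nodes(g, 8, seed=0)
    a = accumulate(g, nodes, seed=4)
    b = accumulate(g, nodes, seed=4)
    assert a.n_pairs == b.n_pairs
    assert a.trace == b.trace
    assert np.array_equal(a.raster.data, b.raster.data)


def test_converged_map_fourfold_symmetric():
    g = grid_graph(np.ones((15, 15)), neighbourhood=8)
    nodes = place_boundary_nodes(g, 12, seed=2)
    cdm = accumulate(g, nodes, threshold=0.999, seed=2, min_pairs=10)
    m = cdm.raster.data
    rot = np.rot90(m)
    asym = np.abs(m - rot).max() / m.max()
    assert asym < 0.05


def test_clip_to_study_area(uniform_raster):
    g = build_graph(uniform_raster)
    nodes = place_boundary_nodes(g, 4, seed=0)
    cdm = accumulate(g, nodes, seed=0, min_pairs=2)
    mask = np.zeros(g.shape)
    mask[3:8, 3:8] = 1.0
    clipped = clip_to_study_area(cdm, Raster(mask))
    assert clipped.clipped
    assert np.isfinite(clipped.raster.data).sum() == 25
    inside = mask == 1.0
    assert np.array_equal(clipped.raster.data[inside], cdm.raster.data[inside])
    identity = clip_to_study_area(cdm, Raster(np.ones(g.shape)))
    assert np.allclose(identity.raster.data, cdm.raster.data, equal_nan=True)
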