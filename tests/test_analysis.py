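import numpy as np
import pandas as pd
import pytest

from landflow import (Raster, CurrentDensityMap, FactorialDesign, standardize,
                      classify, correlation_matrix, agreement_matrix,
                      to_dissimilarity, varpart_dbrda,
                      load_reference_correlations, reanalyze_reference)
from landflow.analysis import StandardizedMap

# vegan::varpart 2.7-1 oracle on the packaged correlation matrix,
# square-rooted 1 - r distances (capscale sqrt.dist analogue):
VEGAN_SQRT = {"water": 48.381071, "scaling": 28.854296, "h_index": 14.557908}
# same oracle, Lingoes-corrected 1 - r distances:
VEGAN_LINGOES = {"water": 39.3, "scaling": 22.6, "h_index": 15.9}


def _smap(data):
    return standardize(Raster(np.asarray(data, dtype=float)))


def test_standardize_population_convention():
    z = _smap([[0.0, 1.0], [2.0, 3.0]]).raster.data
    # mean 1.5, population sd sqrt(1.25)
    expected = (np.array([[0, 1], [2, 3]]) - 1.5) / np.sqrt(1.25)
    assert np.allclose(z, expected)
    assert z.mean() == pytest.approx(0.0, abs=1e-10)
    assert z.std() == pytest.approx(1.0, abs=1e-10)


def test_standardize_preserves_nodata_and_rejects_constant():
    r = Raster(np.array([[1.0, np.nan], [3.0, 5.0]]))
    z = standardize(r)
    assert np.isnan(z.raster.data[0, 1])
    valid = np.isfinite(z.raster.data)
    assert z.raster.data[valid].mean() == pytest.approx(0.0, abs=1e-10)
    with pytest.raises(ValueError):
        standardize(Raster(np.full((3, 3), 2.0)))


def test_classify_threshold_inclusive_and_nested():
    z = _smap(np.arange(100).reshape(10, 10))
    sets = {c: classify(z, c).data == 1.0 for c in (0.0, 1.0, 2.0)}
    assert sets[2.0].sum() <= sets[1.0].sum() <= sets[0.0].sum()
    assert np.all(sets[2.0] <= sets[1.0])
    assert np.all(sets[1.0] <= sets[0.0])
    # ties are classified important
    tie = StandardizedMap(raster=Raster(np.array([[1.0, -1.0]])))
    assert classify(tie, 1.0).data[0, 0] == 1.0


def test_classify_normal_tail_fraction():
    rng = np.random.default_rng(0)
    z = standardize(Raster(rng.standard_normal((250, 400))))
    frac = (classify(z, 2.0).data == 1.0).mean()
    assert frac == pytest.approx(0.0228, abs=0.003)


def test_correlation_matrix_properties():
    rng = np.random.default_rng(1)
    a = rng.standard_normal((50, 200))
    maps = [Raster(a), Raster(-a), Raster(rng.standard_normal((50, 200)))]
    r = correlation_matrix(maps)
    assert np.allclose(r, r.T)
    assert np.allclose(np.diag(r), 1.0)
    assert r[0, 1] == pytest.approx(-1.0)
    assert abs(r[0, 2]) < 0.05   # independent noise fields


def test_correlation_requires_matching_masks():
    a = np.ones((2, 2))
    b = a.copy()
    b[0, 0] = np.nan
    with pytest.raises(ValueError):
        correlation_matrix([Raster(a + np.arange(4).reshape(2, 2)), Raster(b)])


def test_agreement_matrix_counts():
    x = Raster(np.array([[1.0] * 5 + [0.0] * 5] * 10))
    y = Raster(np.where(np.arange(100).reshape(10, 10) < 75, x.data, 1 - x.data))
    m = agreement_matrix([x, y])
    assert m[0, 0] == 1.0
    assert m[0, 1] == pytest.approx(0.75)
    comp = agreement_matrix([x, Raster(1 - x.data)])
    assert comp[0, 1] == 0.0


def test_to_dissimilarity_transforms():
    m = np.array([[1.0, 0.94], [0.94, 1.0]])
    D = to_dissimilarity(m)
    assert D[0, 0] == 0.0
    assert D[0, 1] == pytest.approx(0.06)
    neg = np.array([[1.0, -1.0], [-1.0, 1.0]])
    assert to_dissimilarity(neg)[0, 1] == pytest.approx(2.0)
    assert to_dissimilarity(m, "sqrt")[0, 1] == pytest.approx(np.sqrt(0.06))
    with pytest.raises(ValueError):
        to_dissimilarity(np.array([[1.0, 1.2], [1.2, 1.0]]))


def test_factorial_design_is_full_two_cubed():
    design = FactorialDesign.default()
    assert len(design) == 8
    X = design.dummies()
    M = np.column_stack(list(X.values()))
    assert sorted(map(tuple, M.tolist())) == sorted(
        [(w, s, h) for w in (0, 1) for s in (0, 1) for h in (0, 1)])


def test_varpart_matches_vegan_on_reference_matrix():
    """Against vegan::varpart on the packaged correlation matrix."""
    vp = reanalyze_reference()   # sqrt distances, adjusted R^2
    for factor, expected in VEGAN_SQRT.items():
        assert vp.unique[factor] == pytest.approx(expected, abs=1e-4)
    vp_ling = varpart_dbrda(
        to_dissimilarity(load_reference_correlations().to_numpy()),
        FactorialDesign.default(), correction="lingoes")
    for factor, expected in VEGAN_LINGOES.items():
        assert vp_ling.unique[factor] == pytest.approx(expected, abs=0.05)


def test_varpart_equals_classical_rda_on_euclidean_data():
    """PCoA of Euclidean distances must reproduce raw-data RDA fractions."""
    rng = np.random.default_rng(8)
    design = FactorialDesign.default()
    X = design.dummies()
    data = rng.standard_normal((8, 5))
    D = np.sqrt(((data[:, None, :] - data[None, :, :]) ** 2).sum(-1))
    vp = varpart_dbrda(D, design)

    # classical RDA varpart on the raw data
    from itertools import combinations
    Yc = data - data.mean(0)
    total = np.sum(Yc ** 2)
    names = list(X)

    def adj_r2(sub):
        M = np.column_stack([X[s] for s in sub])
        Mc = M - M.mean(0)
        beta, *_ = np.linalg.lstsq(Mc, Yc, rcond=None)
        r2 = np.sum((Mc @ beta) ** 2) / total
        return 1 - (1 - r2) * 7 / (8 - len(sub) - 1)

    full = adj_r2(tuple(names))
    for f in names:
        others = tuple(n for n in names if n != f)
        assert vp.unique[f] == pytest.approx(100 * (full - adj_r2(others)),
                                             abs=1e-8)


def test_varpart_partition_closure_and_degenerate_cases():
    vp = reanalyze_reference()
    assert sum(vp.unique.values()) + vp.unexplained == pytest.approx(100.0,
                                                                     abs=0.2)
    zero = varpart_dbrda(np.zeros((8, 8)), FactorialDesign.default())
    assert zero.degenerate
    assert zero.unexplained == 100.0
    with pytest.raises(ValueError):
        varpart_dbrda(np.eye(8), FactorialDesign.default())  # nonzero diagonal
    collinear = {"a": np.arange(8.0), "b": 2 * np.arange(8.0)}
    with pytest.raises(ValueError):
        varpart_dbrda(1 - np.eye(8), collinear)


def test_reference_matrix_fixture_shape_and_symmetry():
    corr = load_reference_correlations()
    m = corr.to_numpy()
    assert m.shape == (8, 8)
    assert np.allclose(m, m.T)
    assert np.allclose(np.diag(m), 1.0)
    assert m.min() == pytest.approx(0.34)
    assert np.sort(m[m < 1.0].ravel())[-1] == pytest.approx(0.94)
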