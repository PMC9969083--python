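"""Standardization, correlation, eigen-PCA, Kaiser retention, attribution,
biplot export and the distribution-gated group comparison."""

import numpy as np
import pandas as pd
import pytest

from cpetkit import (
    FeatureMatrix, biplot_export, group_compare, kaiser_retain, pca_eigen,
    pearson_matrix, variance_attribution, zscore,
)
from cpetkit.errors import DataError


def _fm(values, columns=None, groups=None):
    df = pd.DataFrame(values)
    if columns is not None:
        df.columns = columns
    g = None if groups is None else pd.Series(groups, index=df.index)
    return FeatureMatrix(values=df, groups=g)


def _random_fm(rng, n=30, m=6):
    return _fm(rng.normal(size=(n, m)), columns=[f"v{i}" for i in range(m)])


# --------------------------------------------------------------------------
# z-scores

def test_zscore_hand_example_population_sigma():
    fm = _fm({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 9.0]})
    z = zscore(fm)
    assert np.allclose(z.values["a"], [-1.224744871, 0.0, 1.224744871])


def test_zscore_idempotent_and_exactly_standardized(rng):
    fm = _random_fm(rng)
    z1 = zscore(fm)
    z2 = zscore(z1)
    assert np.allclose(z1.values, z2.values, atol=1e-12)
    assert z1.values.mean().abs().max() < 1e-12
    assert (z1.values.std(ddof=0) - 1).abs().max() < 1e-12


def test_zscore_zero_variance_column_named():
    fm = _fm({"ok": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
    with pytest.raises(DataError, match="flat"):
        zscore(fm)


# --------------------------------------------------------------------------
# Pearson matrix

def test_pearson_matrix_structure_and_brute_force(rng):
    fm = _random_fm(rng, n=25, m=5)
    corr = pearson_matrix(fm)
    assert np.allclose(np.diag(corr), 1.0)
    assert np.allclose(corr, corr.T)
    assert (corr.abs() <= 1 + 1e-12).all().all()
    x = fm.values["v1"].to_numpy()
    y = fm.values["v3"].to_numpy()
    r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert corr.loc["v1", "v3"] == pytest.approx(r, rel=1e-12)


def test_pearson_self_and_negation():
    x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
    fm = _fm({"x": x, "neg": -x, "y": x[::-1].copy()})
    corr = pearson_matrix(fm)
    assert corr.loc["x", "x"] == pytest.approx(1.0)
    assert corr.loc["x", "neg"] == pytest.approx(-1.0)


# --------------------------------------------------------------------------
# PCA

def test_two_perfectly_correlated_variables_give_eigenvalues_2_0():
    x = np.array([1.0, 2.0, 5.0, 3.0, 4.0])
    pca = pca_eigen(zscore(_fm({"a": x, "b": 2 * x + 1})))
    assert pca.eigenvalues == pytest.approx([2.0, 0.0], abs=1e-10)
    assert pca.retained_k == 1


def test_pca_rejects_unstandardized_input(rng):
    fm = _random_fm(rng)
    with pytest.raises(DataError, match="standardized"):
        pca_eigen(fm)


def test_loadings_equal_score_variable_correlations(rng):
    z = zscore(_random_fm(rng, n=40, m=6))
    pca = pca_eigen(z)
    for j in range(4):
        pc = f"PC{j+1}"
        for col in z.values.columns:
            r = np.corrcoef(pca.scores[pc], z.values[col])[0, 1]
            assert pca.loadings.loc[col, pc] == pytest.approx(r, abs=1e-8)


def test_eigenvalue_trace_and_reconstruction(rng):
    z = zscore(_random_fm(rng, n=50, m=8))
    pca = pca_eigen(z)
    assert pca.eigenvalues.sum() == pytest.approx(8.0, rel=1e-8)
    recon = pca.scores.to_numpy() @ pca.eigenvectors.to_numpy().T
    assert np.allclose(recon, z.values.to_numpy(), atol=1e-8)
    assert np.abs(pca.scores.mean().to_numpy()).max() < 1e-10


def test_rank_deficiency_reported_when_n_below_m(rng):
    z = zscore(_random_fm(rng, n=10, m=20))
    pca = pca_eigen(z)
    assert pca.effective_rank <= 9
    assert (pca.eigenvalues[pca.effective_rank:] == 0.0).all()


def test_pca_matches_sklearn_covariance_eigenstructure(rng):
    sklearn = pytest.importorskip("sklearn.decomposition")
    z = zscore(_random_fm(rng, n=60, m=7))
    pca = pca_eigen(z)
    sk = sklearn.PCA(n_components=7)
    sk.fit(z.values.to_numpy())
    # sklearn uses divisor n−1 on the already-population-standardized data
    ours = pca.eigenvalues
    theirs = sk.explained_variance_ * (len(z.values) - 1) / len(z.values)
    assert np.allclose(ours, theirs, atol=1e-10)
    for j in range(3):
        a = pca.eigenvectors.to_numpy()[:, j]
        b = sk.components_[j]
        assert abs(abs(a @ b) - 1.0) < 1e-8    # same axes up to sign


def test_sign_convention_deterministic(rng):
    z = zscore(_random_fm(rng, n=30, m=5))
    p1, p2 = pca_eigen(z), pca_eigen(z)
    pd.testing.assert_frame_equal(p1.loadings, p2.loadings)
    for j in range(p1.effective_rank):
        col = p1.loadings.iloc[:, j]
        assert col.loc[col.abs().idxmax()] > 0


def test_row_and_column_permutation_invariance(rng):
    z = zscore(_random_fm(rng, n=30, m=5))
    pca = pca_eigen(z)
    rows = rng.permutation(z.values.index)
    cols = rng.permutation(z.values.columns)
    zp = FeatureMatrix(values=z.values.loc[rows, cols])
    pp = pca_eigen(zp)
    assert np.allclose(pp.eigenvalues, pca.eigenvalues, atol=1e-10)
    pd.testing.assert_frame_equal(pp.scores.loc[z.values.index],
                                  pca.scores, atol=1e-8)
    pd.testing.assert_frame_equal(pp.loadings.loc[z.values.columns],
                                  pca.loadings, atol=1e-8)


def test_independent_columns_eigenvalues_near_one(rng):
    z = zscore(_fm(rng.normal(size=(2000, 10))))
    pca = pca_eigen(z)
    assert pca.eigenvalues.max() < 2.5      # inside the Marchenko–Pastur spread
    assert pca.eigenvalues.min() > 0.3


# --------------------------------------------------------------------------
# Kaiser rule

@pytest.mark.parametrize("ev,expected", [
    ([2.5, 1.2, 0.9, 0.4], 2),
    ([1.0, 1.0], 0),              # strictly greater than one
    ([3.0, 0.0, 0.0], 1),
])
def test_kaiser_counts(ev, expected):
    assert kaiser_retain(np.array(ev)) == expected


def test_kaiser_requires_descending_order():
    with pytest.raises(DataError):
        kaiser_retain(np.array([0.5, 2.0]))


# --------------------------------------------------------------------------
# variance attribution and biplot

def _planted_two_factor(rng, n=200):
    """Two orthogonal latent factors; v0 dominates factor 1, v3 factor 2."""
    f1, f2 = rng.normal(size=(2, n))
    cols = {
        "v0": 1.00 * f1 + 0.05 * rng.normal(size=n),
        "v1": 0.80 * f1 + 0.30 * rng.normal(size=n),
        "v2": 0.70 * f1 + 0.40 * rng.normal(size=n),
        "v3": 1.00 * f2 + 0.05 * rng.normal(size=n),
        "v4": 0.75 * f2 + 0.35 * rng.normal(size=n),
        "target": 0.25 * f1 - 0.20 * f2 + 0.9 * rng.normal(size=n),
    }
    return _fm(cols)


def test_planted_factors_recovered_as_top_contributors(rng):
    pca = pca_eigen(zscore(_planted_two_factor(rng)))
    att = variance_attribution(pca, "target")
    # each retained component is dominated by a variable from its own block
    assert att["top_contributor"].iloc[0] in {"v0", "v1", "v2"}
    assert att["top_contributor"].iloc[1] in {"v3", "v4"}
    assert (att["variance_fraction"].iloc[0]
            >= att["variance_fraction"].iloc[1])


def test_single_factor_concentrates_variance(rng):
    f = rng.normal(size=100)
    fm = _fm({f"v{i}": f + 0.01 * rng.normal(size=100) for i in range(5)})
    pca = pca_eigen(zscore(fm))
    assert pca.variance_fraction[0] == pytest.approx(1.0, abs=0.01)
    assert pca.retained_k == 1
    assert pca.variance_fraction.sum() == pytest.approx(1.0, rel=1e-10)


def test_attribution_unknown_target_rejected(rng):
    pca = pca_eigen(zscore(_random_fm(rng)))
    with pytest.raises(DataError):
        variance_attribution(pca, "no-such-variable")


def test_biplot_tables_shapes_and_axis_swap(rng):
    groups = ["female"] * 9 + ["male"] * 24
    fm = _fm(rng.normal(size=(33, 12)), groups=groups)
    pca = pca_eigen(zscore(fm))
    scores, loadings = biplot_export(pca, 1, 2, groups=fm.groups)
    assert scores.shape == (33, 3)          # PC1, PC2, group
    assert loadings.shape == (12, 2)
    s_swap, l_swap = biplot_export(pca, 2, 1, groups=fm.groups)
    assert np.allclose(s_swap["PC1"], scores["PC1"])
    assert list(s_swap.columns[:2]) == ["PC2", "PC1"]
    pd.testing.assert_series_equal(s_swap["PC2"], scores["PC2"])
    with pytest.raises(DataError):
        biplot_export(pca, 1, 99)


def test_exported_scores_match_pca_scores(rng):
    pca = pca_eigen(zscore(_random_fm(rng)))
    scores, _ = biplot_export(pca, 1, 2)
    pd.testing.assert_frame_equal(scores, pca.scores[["PC1", "PC2"]])


# --------------------------------------------------------------------------
# group comparison

def test_identical_groups_give_null_result(rng):
    base = rng.normal(size=10)
    vals = np.concatenate([base, base])
    fm = _fm({"v": vals, "w": vals + 1.0}, groups=["a"] * 10 + ["b"] * 10)
    res = group_compare(fm)[0]
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0, abs=1e-9)
    assert res.test in ("unpaired-t", "welch-t", "mann-whitney")


def test_skewed_variable_routes_to_mann_whitney(rng):
    a = np.exp(rng.normal(0, 1.5, size=40))     # heavily lognormal
    b = np.exp(rng.normal(0.5, 1.5, size=40))
    both = np.concatenate([a, b])
    fm = _fm({"v": both, "w": rng.normal(size=80)}, groups=["a"] * 40 + ["b"] * 40)
    res = group_compare(fm)[0]
    assert res.test == "mann-whitney"
    assert res.shapiro_p_a < 0.05


def test_normal_unequal_variance_routes_to_welch(rng):
    a = rng.normal(0, 1.0, size=60)
    b = rng.normal(0.3, 4.0, size=60)
    both = np.concatenate([a, b])
    fm = _fm({"v": both, "w": rng.normal(size=120)}, groups=["a"] * 60 + ["b"] * 60)
    res = group_compare(fm)[0]
    assert res.levene_p < 0.05
    assert res.test == "welch-t"


def test_group_compare_requires_two_groups(rng):
    fm = _fm({"v": rng.normal(size=9), "w": rng.normal(size=9)}, groups=["a"] * 9)
    with pytest.raises(DataError):
        group_compare(fm)
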