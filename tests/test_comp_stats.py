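"""ILR transform, Hotelling's T-squared, post-hoc t-tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from paralogshare.comp_stats import (
    aitchison_distance,
    bonferroni_threshold,
    hotelling_one_sample,
    ilr_basis,
    ilr_inverse,
    ilr_matrix,
    ilr_transform,
    multiplicative_zero_replacement,
    posthoc_pairwise,
)

simplex = st.lists(st.floats(0.01, 1.0), min_size=3, max_size=6).map(
    lambda v: np.array(v) / np.sum(v))


def test_uniform_maps_to_origin():
    coords = ilr_transform(np.array([1 / 3, 1 / 3, 1 / 3])).coords
    assert np.allclose(coords, 0.0, atol=1e-12)


def test_basis_is_orthonormal_and_zero_sum():
    for d in (2, 3, 5):
        v = ilr_basis(d)
        assert np.allclose(v.T @ v, np.eye(d - 1), atol=1e-12)
        assert np.allclose(v.sum(axis=0), 0.0, atol=1e-12)


def test_sequential_formula_matches_matrix_oracle():
    """The sequential formula equals V' log x for the orthonormal contrast
    matrix V (two independent formulations of the same map)."""
    rng = np.random.default_rng(4)
    for _ in range(50):
        x = rng.dirichlet(np.ones(4))
        seq = ilr_transform(x).coords
        matrix_form = ilr_basis(4).T @ np.log(x)
        assert np.allclose(seq, matrix_form, atol=1e-12)


def test_known_composition_coordinates():
    x = np.array([0.5, 0.25, 0.25])
    expected = ilr_basis(3).T @ np.log(x)
    assert np.allclose(ilr_transform(x).coords, expected, atol=1e-12)


@settings(derandomize=True, max_examples=100)
@given(simplex)
def test_ilr_roundtrip(x):
    back = ilr_inverse(ilr_transform(x).coords)
    assert np.allclose(back, x, atol=1e-9)


@settings(derandomize=True, max_examples=50)
@given(simplex, simplex)
def test_ilr_is_an_isometry(x, y):
    """Aitchison distance equals Euclidean distance of ILR coordinates,
    computed here independently from the centred log-ratio definition."""
    if len(x) != len(y):
        return
    clr = lambda z: np.log(z) - np.log(z).mean()
    d_ait = np.linalg.norm(clr(x) - clr(y))
    assert aitchison_distance(x, y) == pytest.approx(d_ait, abs=1e-9)


def test_ilr_agrees_with_scikit_bio_up_to_basis():
    """Cross-check against scikit-bio's ILR: coordinate norms and pairwise
    distances are basis-invariant, so they must agree even if the
    orthonormal contrast bases differ."""
    from skbio.stats.composition import ilr as skbio_ilr

    rng = np.random.default_rng(19)
    for _ in range(10):
        x = rng.dirichlet([3, 2, 4, 1])
        y = rng.dirichlet([3, 2, 4, 1])
        mine_x, mine_y = ilr_transform(x).coords, ilr_transform(y).coords
        skb_x, skb_y = skbio_ilr(x), skbio_ilr(y)
        assert np.linalg.norm(mine_x) == pytest.approx(
            np.linalg.norm(skb_x), abs=1e-9)
        assert np.linalg.norm(mine_x - mine_y) == pytest.approx(
            np.linalg.norm(skb_x - skb_y), abs=1e-9)


def test_zero_part_rejected_and_replacement_strategy():
    with pytest.raises(ValueError, match="zero"):
        ilr_transform(np.array([0.5, 0.5, 0.0]))
    fixed = multiplicative_zero_replacement(np.array([[0.5, 0.5, 0.0]]), 1e-4)
    assert np.all(fixed > 0)
    assert fixed.sum() == pytest.approx(1.0)


def test_hotelling_zero_at_null_mean():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(20, 2))
    res = hotelling_one_sample(x - x.mean(axis=0))
    assert res.statistic == pytest.approx(0.0, abs=1e-18)
    assert res.p == pytest.approx(1.0)


def test_hotelling_reduces_to_squared_t_in_1d():
    rng = np.random.default_rng(2)
    x = rng.normal(0.4, 1.0, size=30)
    res = hotelling_one_sample(x[:, None])
    t, p = stats.ttest_1samp(x, 0.0)
    assert res.statistic == pytest.approx(t ** 2, rel=1e-10)
    assert res.p == pytest.approx(p, rel=1e-10)


def test_hotelling_invariant_under_part_permutation():
    """The p-value must not depend on the order of the composition's parts."""
    rng = np.random.default_rng(7)
    comps = rng.dirichlet([4, 3, 2], size=40)
    p_ref = hotelling_one_sample(ilr_matrix(comps)).p
    for perm in ([1, 0, 2], [2, 1, 0], [1, 2, 0]):
        p_perm = hotelling_one_sample(ilr_matrix(comps[:, perm])).p
        assert p_perm == pytest.approx(p_ref, abs=1e-9)


def test_hotelling_requires_enough_samples():
    with pytest.raises(ValueError):
        hotelling_one_sample(np.zeros((2, 2)))


def test_hotelling_singular_covariance_rejected():
    x = np.tile(np.array([[1.0, 2.0]]), (10, 1))
    with pytest.raises(ValueError, match="singular"):
        hotelling_one_sample(x)


def test_posthoc_identical_parts_p_one():
    comps = np.tile(np.array([0.4, 0.4, 0.2]), (10, 1))
    res = posthoc_pairwise(comps, ["a", "b", "c"], pairs=[("a", "b")])
    assert res[0].p == 1.0 and res[0].degenerate


def test_posthoc_closed_form_t():
    # differences (1, 2, 3) against 0: t = 2 / (1/sqrt(3)) = 3.464..., p ~ 0.0742
    base = np.array([[0.4, 0.3, 0.3], [0.45, 0.25, 0.3], [0.5, 0.2, 0.3]])
    diffs = base[:, 0] - base[:, 1]  # 0.1, 0.2, 0.3 (scaled copy of 1,2,3)
    res = posthoc_pairwise(base, ["a", "b", "c"], pairs=[("a", "b")])
    t_expected = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(3))
    assert res[0].statistic == pytest.approx(t_expected, rel=1e-10)
    assert t_expected == pytest.approx(2 * np.sqrt(3), rel=1e-10)
    assert res[0].p == pytest.approx(2 * stats.t.sf(2 * np.sqrt(3), df=2), rel=1e-10)
    assert res[0].p == pytest.approx(0.0742, abs=5e-4)


def test_posthoc_zero_variance_nonzero_mean():
    comps = np.tile(np.array([0.5, 0.3, 0.2]), (5, 1))
    res = posthoc_pairwise(comps, ["a", "b", "c"], pairs=[("a", "b")])
    assert res[0].p == 0.0 and res[0].degenerate


def test_posthoc_at_study_means_all_significant():
    """At the left-ventricle mean shares with modest spread, every pairwise
    difference clears the 0.05/3 threshold."""
    rng = np.random.default_rng(10)
    from paralogshare.comp_stats import ilr_basis as basis
    center = ilr_matrix(np.array([[0.368, 0.419, 0.213]]))[0]
    coords = rng.normal(center, 0.1, size=(100, 2))
    comps = np.exp(coords @ basis(3).T)
    comps /= comps.sum(axis=1, keepdims=True)
    res = posthoc_pairwise(comps, ["CALM1", "CALM2", "CALM3"])
    assert all(r.significant for r in res)
    means = comps.mean(axis=0)
    assert means[1] > means[0] > means[2]


def test_bonferroni_threshold():
    assert bonferroni_threshold(0.05, 3) == pytest.approx(0.05 / 3)
    with pytest.raises(ValueError):
        bonferroni_threshold(0.05, 0)
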