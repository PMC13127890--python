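"""Size factors, translational efficiency, paired tests and correlations."""

import numpy as np
import pytest
from itertools import product
from scipy import stats

from paralogshare.io_formats import CountMatrix
from paralogshare.translation import (
    TEMatrix,
    _paired_wilcoxon,
    estimate_size_factors,
    estimate_size_factors_matrix,
    pairwise_te_correlation,
    pairwise_te_tests,
    translational_efficiency,
)
from paralogshare.synthetic_data import SimulationConfig, simulate_dataset


def oracle_size_factors(counts):
    """Straight-line median-of-ratios reimplementation (no shared code)."""
    counts = np.asarray(counts, dtype=float)
    keep = [i for i in range(counts.shape[0]) if (counts[i] > 0).all()]
    ref = counts[keep]
    out = []
    for j in range(counts.shape[1]):
        ratios = []
        for i in range(ref.shape[0]):
            geo = np.exp(np.mean([np.log(ref[i, k]) for k in range(counts.shape[1])]))
            ratios.append(ref[i, j] / geo)
        out.append(np.median(ratios))
    return np.array(out)


def test_size_factors_identical_columns_equal():
    counts = np.tile(np.array([[10.0], [20.0], [5.0]]), (1, 3))
    sf = estimate_size_factors_matrix(counts)
    assert np.allclose(sf, sf[0])


def test_size_factors_scaling_property():
    rng = np.random.default_rng(1)
    col = rng.poisson(100, size=20).astype(float) + 1
    counts = np.column_stack([col, 2 * col])
    sf = estimate_size_factors_matrix(counts)
    assert sf[1] / sf[0] == pytest.approx(2.0, rel=1e-12)


def test_size_factors_match_oracle_random_matrix():
    rng = np.random.default_rng(42)
    counts = rng.poisson(50, size=(50, 6)).astype(float) + 1
    assert np.allclose(estimate_size_factors_matrix(counts),
                       oracle_size_factors(counts), atol=1e-12)


def test_size_factors_error_without_common_positive_gene():
    counts = np.array([[0.0, 5.0], [5.0, 0.0]])
    with pytest.raises(ValueError, match="pseudocount"):
        estimate_size_factors_matrix(counts)


def _tiny_pair():
    rna = CountMatrix(["a", "b"], ["s1"], np.array([[10.0], [20.0]]), "rna")
    ribo = CountMatrix(["a", "b"], ["s1"], np.array([[30.0], [20.0]]), "ribo")
    return rna, ribo


def test_te_ratio_and_zero_rna_missing():
    rna, ribo = _tiny_pair()
    sf = estimate_size_factors(rna, ribo)
    # force unit factors to check the raw ratio contract
    sf.factors = {k: 1.0 for k in sf.factors}
    te = translational_efficiency(rna, ribo, sf)
    assert te.te[0, 0] == pytest.approx(3.0)
    rna0 = CountMatrix(["a", "b"], ["s1"], np.array([[0.0], [20.0]]), "rna")
    te0 = translational_efficiency(rna0, ribo, sf)
    assert np.isnan(te0.te[0, 0])


def test_te_invariant_to_joint_sample_rescaling():
    """Scaling both assays of one sample by c leaves its TE unchanged."""
    rng = np.random.default_rng(8)
    counts_r = rng.poisson(100, size=(30, 4)).astype(float) + 1
    counts_b = rng.poisson(80, size=(30, 4)).astype(float) + 1
    genes = [f"g{i}" for i in range(30)]
    samples = [f"s{j}" for j in range(4)]
    rna = CountMatrix(genes, samples, counts_r, "rna")
    ribo = CountMatrix(genes, samples, counts_b, "ribo")
    te1 = translational_efficiency(rna, ribo, estimate_size_factors(rna, ribo))
    c = 3.7
    rna2 = CountMatrix(genes, samples, counts_r * np.array([c, 1, 1, 1]), "rna")
    ribo2 = CountMatrix(genes, samples, counts_b * np.array([c, 1, 1, 1]), "ribo")
    te2 = translational_efficiency(rna2, ribo2, estimate_size_factors(rna2, ribo2))
    assert np.allclose(te1.te, te2.te, rtol=1e-9)


def test_te_recovery_from_generator():
    ds = simulate_dataset(SimulationConfig(n_samples=80, seed=2))
    sf = estimate_size_factors(ds.rna_cds, ds.ribo)
    te = translational_efficiency(ds.rna_cds, ds.ribo, sf)
    med = te.median_te()
    for gene, true in ds.truth.te.items():
        assert med[gene] == pytest.approx(true, rel=0.10)


# --- Wilcoxon signed-rank -------------------------------------------------

def sign_enumeration_p(diffs):
    """Exact two-sided p by enumerating all sign assignments of |diffs|."""
    mags = np.abs(diffs)
    ranks = stats.rankdata(mags)
    w_plus = ranks[diffs > 0].sum()
    total = ranks.sum()
    w_obs_min, w_obs_max = min(w_plus, total - w_plus), max(w_plus, total - w_plus)
    count = 0
    n = len(diffs)
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= w_obs_min + 1e-9 or w >= w_obs_max - 1e-9:
            count += 1
    return count / 2 ** n


def test_wilcoxon_identical_pairs_degenerate():
    stat, p, degenerate = _paired_wilcoxon(np.arange(8.0), np.arange(8.0))
    assert p == 1.0 and degenerate


def test_wilcoxon_n6_all_positive_exact():
    _, p, _ = _paired_wilcoxon(np.array([2., 3., 4., 5., 6., 7.]),
                               np.array([1., 1., 1., 1., 1., 1.]))
    assert p == pytest.approx(0.03125, abs=1e-12)


def test_wilcoxon_exact_matches_sign_enumeration():
    rng = np.random.default_rng(17)
    for n in (6, 8, 10):
        for _ in range(5):
            diffs = rng.normal(0.3, 1.0, size=n)
            # tie-free magnitudes with probability 1 under a continuous draw
            _, p, _ = _paired_wilcoxon(diffs, np.zeros(n))
            assert p == pytest.approx(sign_enumeration_p(diffs), abs=1e-12)


def test_pairwise_te_tests_threshold_and_labels():
    rng = np.random.default_rng(6)
    te = TEMatrix(["a", "b", "c"], [f"s{i}" for i in range(20)],
                  rng.lognormal(0, 0.3, size=(3, 20)))
    results = pairwise_te_tests(te)
    assert len(results) == 3
    assert all(r.threshold == pytest.approx(0.05 / 3) for r in results)


def test_wilcoxon_type_one_error_calibrated():
    """Under H0 (paired samples from one distribution) rejections at
    alpha=0.05 stay near 0.05."""
    rng = np.random.default_rng(99)
    rejections = 0
    reps = 1000
    for _ in range(reps):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        _, p, _ = _paired_wilcoxon(x, y)
        rejections += p < 0.05
    assert abs(rejections / reps - 0.05) <= 0.019  # 3 binomial sd


# --- Spearman -------------------------------------------------------------

def test_spearman_monotone_and_reversed():
    x = np.arange(10.0)
    te = TEMatrix(["a", "b", "c"], [f"s{i}" for i in range(10)],
                  np.vstack([x, x ** 2 + 1, x[::-1]]))
    res = {r.df: r for r in pairwise_te_correlation(te)}
    assert res[("a", "b")].statistic == pytest.approx(1.0)
    assert res[("a", "c")].statistic == pytest.approx(-1.0)


def test_spearman_constant_vector_flagged():
    te = TEMatrix(["a", "b"], [f"s{i}" for i in range(8)],
                  np.vstack([np.full(8, 2.0), np.arange(8.0)]))
    (res,) = pairwise_te_correlation(te)
    assert res.degenerate and np.isnan(res.statistic)


def test_spearman_recovers_rank_correlation():
    """Bivariate normal with correlation 0.31 -> mean rho near 0.3."""
    rng = np.random.default_rng(12)
    rhos = []
    for _ in range(300):
        z = rng.multivariate_normal([0, 0], [[1, 0.31], [0.31, 1]], size=80)
        rho, _ = stats.spearmanr(z[:, 0], z[:, 1])
        rhos.append(rho)
    assert np.mean(rhos) == pytest.approx(0.30, abs=0.02)
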