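"""Compositional hypothesis testing on the Aitchison simplex.

Per-sample gene-family fractions sum to 1, so their parts are statistically
dependent and classical multivariate tests cannot be applied directly.
The isometric log-ratio (ILR) transform maps a D-part composition to D-1
unconstrained coordinates via an orthonormal log-contrast basis; the
uniform composition maps to the origin.  A one-sample Hotelling's T²
on the ILR coordinates then tests whether the mean composition differs
from a hypothesized one (by default: uniform), and one-sample t-tests on
per-sample differences of fractions localize which parts drive the
difference.  The Hotelling p-value is invariant to the basis choice and
to permutations of the parts; the coordinates themselves depend on the
basis, which is therefore fixed and recorded.

Multiple testing follows the divide-by-n rule: a result is significant
when p < alpha / n_tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    method: str
    statistic: float
    df: object  # degrees of freedom or the pair of labels tested
    p: float
    threshold: float
    significant: bool
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Significance threshold alpha divided by the number of tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


# ---------------------------------------------------------------------------
# ILR
# ---------------------------------------------------------------------------

def ilr_basis(d: int) -> np.ndarray:
    """Orthonormal sequential-binary contrast matrix, shape (d, d-1).

    Column i (1-based) contrasts the geometric mean of parts 1..i against
    part i+1; columns are orthonormal and each sums to zero, so
    ``V.T @ log(x)`` equals the sequential ILR formula.
    """
    if d < 2:
        raise ValueError("need at least a 2-part composition")
    v = np.zeros((d, d - 1))
    for i in range(1, d):
        scale = np.sqrt(i / (i + 1.0))
        v[:i, i - 1] = scale / i
        v[i, i - 1] = -scale
    return v


@dataclass
class ILRCoordinates:
    sample_id: str
    coords: np.ndarray
    basis_id: str = "sequential-binary"


def ilr_transform(fractions: np.ndarray, sample_id: str = "",
                  basis_id: str = "sequential-binary") -> ILRCoordinates:
    """Map a strictly positive composition to D-1 ILR coordinates.

    coords_i = sqrt(i/(i+1)) * ln(gmean(x_1..x_i) / x_{i+1}).  Zero parts
    are rejected: silently imputing them would bias every downstream test,
    so zero replacement must be an explicit, separate step (see
    :func:`multiplicative_zero_replacement`).
    """
    x = np.asarray(fractions, dtype=float)
    if np.any(x <= 0):
        raise ValueError(
            "composition has zero/negative parts; apply a zero-replacement "
            "strategy (e.g. multiplicative_zero_replacement) first")
    d = len(x)
    coords = np.empty(d - 1)
    logx = np.log(x)
    for i in range(1, d):
        gm = logx[:i].mean()
        coords[i - 1] = np.sqrt(i / (i + 1.0)) * (gm - logx[i])
    return ILRCoordinates(sample_id, coords, basis_id)


def ilr_inverse(coords: np.ndarray) -> np.ndarray:
    """Inverse ILR: coordinates back to a unit-sum composition."""
    coords = np.asarray(coords, dtype=float)
    v = ilr_basis(len(coords) + 1)
    logx = v @ coords
    x = np.exp(logx)
    return x / x.sum()


def ilr_matrix(comps: np.ndarray) -> np.ndarray:
    """Row-wise ILR of an n x D matrix of compositions -> n x (D-1)."""
    comps = np.asarray(comps, dtype=float)
    if np.any(comps <= 0):
        raise ValueError("compositions must be strictly positive for ILR")
    return np.log(comps) @ ilr_basis(comps.shape[1])


def multiplicative_zero_replacement(comps: np.ndarray, epsilon: float) -> np.ndarray:
    """Replace zeros by epsilon, shrinking nonzero parts multiplicatively."""
    comps = np.asarray(comps, dtype=float).copy()
    for row in comps:
        zeros = row == 0
        if zeros.any():
            row[zeros] = epsilon
            row[~zeros] *= 1.0 - zeros.sum() * epsilon
    return comps / comps.sum(axis=1, keepdims=True)


def aitchison_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Aitchison distance = Euclidean distance in ILR coordinates."""
    cx = ilr_transform(x).coords
    cy = ilr_transform(y).coords
    return float(np.linalg.norm(cx - cy))


# ---------------------------------------------------------------------------
# Hotelling's T-squared
# ---------------------------------------------------------------------------

def hotelling_one_sample(
    coords: np.ndarray,
    mu0: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    n_tests: int = 1,
) -> TestResult:
    """One-sample Hotelling's T² of a mean vector against mu0.

    ``coords`` is n x p (e.g. ILR coordinates); ``mu0`` defaults to the
    origin, i.e. the ILR image of the uniform composition.  The statistic
    T² = n (x̄-mu0)' S⁻¹ (x̄-mu0) is referred to an F(p, n-p) distribution
    via F = (n-p) / (p (n-1)) T².
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n, p = x.shape
    if mu0 is None:
        mu0 = np.zeros(p)
    mu0 = np.asarray(mu0, dtype=float)
    if n <= p:
        raise ValueError(f"need n > p (got n={n}, p={p})")
    diff = x.mean(axis=0) - mu0
    s = np.cov(x, rowvar=False).reshape(p, p)
    sign, logdet = np.linalg.slogdet(s)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular sample covariance; Hotelling T² undefined")
    t2 = float(n * diff @ np.linalg.solve(s, diff))
    f_stat = (n - p) / (p * (n - 1.0)) * t2
    pval = float(stats.f.sf(f_stat, p, n - p))
    threshold = bonferroni_threshold(alpha, n_tests)
    return TestResult(
        method="hotelling_t2", statistic=t2, df=(p, n - p), p=pval,
        threshold=threshold, significant=pval < threshold,
        extra={"F": f_stat, "n": n},
    )


# ---------------------------------------------------------------------------
# post-hoc t-tests
# ---------------------------------------------------------------------------

def posthoc_pairwise(
    comps: np.ndarray,
    parts: Sequence[str],
    pairs: Optional[Sequence[tuple[str, str]]] = None,
    alpha: float = 0.05,
    on: str = "fractions",
) -> list[TestResult]:
    """One-sample t-tests locating which parts differ.

    Default construction (``on="fractions"``): for each pair (i, j), test
    the per-sample differences fraction_i - fraction_j against 0 — a
    paired t-test.  ``on="ilr"`` instead tests pairwise log-ratio
    coordinates sqrt(1/2) ln(x_i/x_j) against 0.
    """
    comps = np.asarray(comps, dtype=float)
    n, d = comps.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    if pairs is None:
        pairs = list(combinations(parts, 2))
    idx = {g: k for k, g in enumerate(parts)}
    threshold = bonferroni_threshold(alpha, len(pairs))
    results = []
    for g1, g2 in pairs:
        if on == "fractions":
            diffs = comps[:, idx[g1]] - comps[:, idx[g2]]
        elif on == "ilr":
            diffs = np.sqrt(0.5) * np.log(comps[:, idx[g1]] / comps[:, idx[g2]])
        else:
            raise ValueError(f"unknown post-hoc space {on!r}")
        if np.ptp(diffs) == 0:
            # zero variance: p degenerates to 0 or 1 by the mean's sign
            mean = diffs.mean()
            p = 1.0 if mean == 0 else 0.0
            results.append(TestResult(
                method="one_sample_t", statistic=0.0 if mean == 0 else np.inf,
                df=(g1, g2), p=p, threshold=threshold,
                significant=p < threshold, degenerate=True))
            continue
        t, p = stats.ttest_1samp(diffs, 0.0)
        results.append(TestResult(
            method="one_sample_t", statistic=float(t), df=(g1, g2),
            p=float(p), threshold=threshold, significant=p < threshold,
            extra={"mean_diff": float(diffs.mean()), "n": n}))
    return results
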