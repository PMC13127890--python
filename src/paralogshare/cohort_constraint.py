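"""Gene-specific variant-consequence statistics.

Two complementary views of how missense variants play out per gene:

* cohort contingency tests — does the fraction of carriers with a cardiac
  event differ among genes?  Pearson chi-squared for r x 2 tables (no
  continuity correction; that correction applies only to 2 x 2) and an
  exact Fisher-style test by complete enumeration of margin-fixed tables
  for small cohorts.

* population constraint — observed/expected (o/e) variant counts with
  confidence intervals from a normalized Poisson likelihood over a grid
  of candidate ratios, the convention used for gnomAD-style constraint
  metrics.  o/e well below 1 indicates negative selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np
import pandas as pd
from scipy import stats

from .comp_stats import TestResult, bonferroni_threshold
from .io_formats import CohortTable, ConstraintRecord

#: the any-cardiac-event table from the International Calmodulinopathy
#: Registry (missense carriers with / without an event per gene)
REGISTRY_ANY_EVENT = pd.DataFrame({
    "gene_id": ["CALM1", "CALM2", "CALM3"],
    "with_event": [46, 37, 20],
    "without_event": [6, 16, 15],
})


def registry_any_event_table() -> CohortTable:
    """The published registry 3 x 2 any-cardiac-event table."""
    return CohortTable(REGISTRY_ANY_EVENT.copy(), phenotype_label="all")


def chi_squared_test(table: CohortTable, alpha: float = 0.05,
                     n_tests: int = 1) -> TestResult:
    """Pearson chi-squared on an r x 2 cohort table, df = r - 1."""
    arr = table.as_array()
    if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
        raise ValueError("zero marginal total; chi-squared undefined")
    chi2, p, dof, _expected = stats.chi2_contingency(arr, correction=False)
    threshold = bonferroni_threshold(alpha, n_tests)
    return TestResult(
        method="chi_squared", statistic=float(chi2), df=int(dof), p=float(p),
        threshold=threshold, significant=p < threshold)


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def _table_log_prob(col1: tuple[int, ...], row_totals: np.ndarray,
                    col1_total: int, n_total: int) -> float:
    """Multivariate hypergeometric log-probability of an r x 2 table."""
    lp = -_log_comb(n_total, col1_total)
    for a, r in zip(col1, row_totals):
        lp += _log_comb(int(r), int(a))
    return lp


def fisher_exact_test(table: CohortTable, alpha: float = 0.05,
                      n_tests: int = 1, max_total: int = 200) -> TestResult:
    """Exact test on an r x 2 table by full margin-fixed enumeration.

    The p-value sums the hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed the observed
    table's (with a relative tolerance of 1e-7 for ties, as is
    conventional for exact tests on floating-point probabilities).
    """
    arr = table.as_array()
    n_total = int(arr.sum())
    if n_total > max_total:
        raise ValueError(
            f"table total {n_total} exceeds enumeration limit {max_total}; "
            "use chi_squared_test")
    row_totals = arr.sum(axis=1)
    col1_total = int(arr[:, 0].sum())
    obs_lp = _table_log_prob(tuple(arr[:, 0]), row_totals, col1_total, n_total)
    cutoff = obs_lp + 1e-7
    p = 0.0
    ranges = [range(int(r) + 1) for r in row_totals]
    for col1 in iter_product(*ranges):
        if sum(col1) != col1_total:
            continue
        lp = _table_log_prob(col1, row_totals, col1_total, n_total)
        if lp <= cutoff:
            p += math.exp(lp)
    p = min(p, 1.0)
    threshold = bonferroni_threshold(alpha, n_tests)
    return TestResult(
        method="fisher_exact", statistic=math.exp(obs_lp), df=arr.shape, p=p,
        threshold=threshold, significant=p < threshold)


def _report_integer_percent(pct: np.ndarray) -> np.ndarray:
    """Half-up rounding via the one-decimal display value.

    Clinical tables typically round the percentage shown at one decimal
    (88.46 -> 88.5 -> 89), so the integer report is derived from that
    intermediate, not from the raw value.
    """
    one_dp = np.floor(pct * 10.0 + 0.5) / 10.0
    return np.floor(one_dp + 0.5)


def event_percentages(table: CohortTable) -> pd.DataFrame:
    """Percent of carriers with an event per gene (exact and rounded)."""
    df = table.table.copy()
    totals = df["with_event"] + df["without_event"]
    pct = np.where(totals > 0, 100.0 * df["with_event"] / totals, np.nan)
    if (totals == 0).any():
        import logging
        logging.getLogger("paralogshare").warning("zero-total cohort row")
    df["n"] = totals
    df["percent_with_event"] = pct
    df["percent_rounded"] = pd.Series(_report_integer_percent(pct)).astype("Int64")
    return df


# ---------------------------------------------------------------------------
# observed/expected constraint ratios
# ---------------------------------------------------------------------------

@dataclass
class OERatio:
    gene_id: str
    variant_class: str
    observed: int
    expected: float
    ratio: float
    ci_lo: float
    ci_hi: float
    ci_level: float = 0.90


def oe_ratio_ci(
    rec: ConstraintRecord,
    ci_level: float = 0.90,
    grid_max: float = 10.0,
    grid_step: float = 1e-3,
) -> OERatio:
    """o/e ratio with a normalized-likelihood confidence interval.

    The likelihood of ratio r is the Poisson pmf of the observed count at
    mean r x expected, evaluated on a grid over [0, grid_max], normalized
    to unit sum.  The CI endpoints are the grid values where the
    cumulative normalized likelihood crosses (1-level)/2 and
    1-(1-level)/2.  For observed = 0 the interval is one-sided:
    ci_lo = 0 and ci_hi is the `level + (1-level)/2` upper crossing
    (0.95 for a 90% interval).
    """
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    grid = np.arange(0.0, grid_max + grid_step / 2, grid_step)
    mean = grid * rec.expected
    if rec.observed == 0:
        loglik = -mean  # pmf(0; m) = exp(-m)
    else:
        with np.errstate(divide="ignore"):
            logm = np.where(mean > 0, np.log(mean), -np.inf)
        loglik = rec.observed * logm - mean
    loglik -= loglik.max()
    lik = np.exp(loglik)
    cum = np.cumsum(lik) / lik.sum()
    upper_q = 1.0 - (1.0 - ci_level) / 2.0
    if rec.observed == 0:
        ci_lo = 0.0
        ci_hi = float(grid[np.searchsorted(cum, upper_q)])
    else:
        lower_q = (1.0 - ci_level) / 2.0
        ci_lo = float(grid[np.searchsorted(cum, lower_q)])
        ci_hi = float(grid[np.searchsorted(cum, upper_q)])
    return OERatio(
        gene_id=rec.gene_id, variant_class=rec.variant_class,
        observed=rec.observed, expected=rec.expected,
        ratio=rec.observed / rec.expected, ci_lo=ci_lo, ci_hi=ci_hi,
        ci_level=ci_level)


def oe_table(records, ci_level: float = 0.90) -> pd.DataFrame:
    """o/e ratios and CIs for a list of constraint records, 2-dp bounds."""
    rows = []
    for rec in records:
        oe = oe_ratio_ci(rec, ci_level=ci_level)
        rows.append({
            "gene_id": oe.gene_id, "variant_class": oe.variant_class,
            "observed": oe.observed, "expected": oe.expected,
            "oe": round(oe.ratio, 2), "ci_lo": round(oe.ci_lo, 2),
            "ci_hi": round(oe.ci_hi, 2), "ci_level": oe.ci_level,
        })
    return pd.DataFrame(rows)
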