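"""Translational efficiency from paired RNA-seq and ribosome profiling.

The two assays are depth-normalized *together*: their columns enter one
joint matrix and median-of-ratios size factors are estimated per column,
so the ribo/RNA ratio is comparable across assays.  Translational
efficiency (TE) per gene and sample is then

    TE = (ribo / sf_ribo) / (rna / sf_rna)

with no gene-length adjustment — the inputs are CDS-mapped counts and the
CDS lengths of the genes under study are identical.  TE is undefined
(missing, never infinite) where the normalized RNA count is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix
from .comp_stats import TestResult, bonferroni_threshold


@dataclass
class SizeFactors:
    """Per-column depth factors; keys are ``"{sample}:{assay}"``."""

    factors: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.factors.values()):
            raise ValueError("size factors must be strictly positive")

    def __getitem__(self, key: str) -> float:
        return self.factors[key]


def _median_of_ratios(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors for a genes x columns matrix.

    Per column: median over reference genes of count / geometric-mean of
    that gene's row; only genes positive in every column are usable as
    references.
    """
    counts = np.asarray(counts, dtype=float)
    all_positive = np.all(counts > 0, axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every column; size factors are "
            "undefined (consider a pseudocount)")
    ref = counts[all_positive]
    geo_mean = np.exp(np.mean(np.log(ref), axis=1, keepdims=True))
    # median taken in ratio space: with an even number of reference genes
    # the median interpolates, which does not commute with exp(log .)
    return np.median(ref / geo_mean, axis=0)


def estimate_size_factors(rna: CountMatrix, ribo: CountMatrix) -> SizeFactors:
    """Joint size factors over the concatenated RNA and ribo columns."""
    if rna.genes != ribo.genes:
        raise ValueError("RNA and ribo matrices must share gene order")
    joint = np.hstack([rna.counts, ribo.counts])
    sf = _median_of_ratios(joint)
    keys = [f"{s}:rna" for s in rna.samples] + [f"{s}:ribo" for s in ribo.samples]
    return SizeFactors(dict(zip(keys, sf)))


def estimate_size_factors_matrix(counts: np.ndarray) -> np.ndarray:
    """Size factors for a bare matrix (column order preserved)."""
    return _median_of_ratios(counts)


@dataclass
class TEMatrix:
    genes: list[str]
    samples: list[str]
    te: np.ndarray  # genes x samples, NaN where RNA count is 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.te, index=self.genes, columns=self.samples)

    def median_te(self) -> pd.Series:
        """Per-gene median TE across samples, ignoring missing values."""
        return self.to_frame().median(axis=1, skipna=True)


def translational_efficiency(
    rna: CountMatrix, ribo: CountMatrix, sf: SizeFactors
) -> TEMatrix:
    if rna.genes != ribo.genes or rna.samples != ribo.samples:
        raise ValueError("RNA and ribo matrices must share genes and samples")
    sf_rna = np.array([sf[f"{s}:rna"] for s in rna.samples])
    sf_ribo = np.array([sf[f"{s}:ribo"] for s in ribo.samples])
    norm_rna = rna.counts / sf_rna
    norm_ribo = ribo.counts / sf_ribo
    with np.errstate(divide="ignore", invalid="ignore"):
        te = np.where(norm_rna > 0, norm_ribo / norm_rna, np.nan)
    return TEMatrix(list(rna.genes), list(rna.samples), te)


def _paired_wilcoxon(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Two-sided paired signed-rank test; exact null for small tie-free n.

    Zero differences are dropped (standard signed-rank convention).
    Returns (statistic, p, degenerate) where degenerate marks the
    all-differences-zero case (p = 1 by convention).
    """
    d = x - y
    d = d[np.isfinite(d)]
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return 0.0, 1.0, True
    ranks_tied = len(np.unique(np.abs(nonzero))) < len(nonzero)
    method = "exact" if (len(nonzero) <= 25 and not ranks_tied) else "approx"
    res = stats.wilcoxon(nonzero, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), False


def pairwise_te_tests(
    te: TEMatrix, alpha: float = 0.05, pairs: Optional[Sequence[tuple[str, str]]] = None
) -> list[TestResult]:
    """Paired Wilcoxon signed-rank tests between genes' per-sample TEs.

    Significance uses the Bonferroni-by-division threshold alpha/n_tests.
    """
    df = te.to_frame()
    if pairs is None:
        pairs = list(combinations(te.genes, 2))
    threshold = bonferroni_threshold(alpha, len(pairs))
    results = []
    for g1, g2 in pairs:
        x, y = df.loc[g1].to_numpy(), df.loc[g2].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 6:
            raise ValueError(f"fewer than 6 complete pairs for {g1} vs {g2}")
        stat, p, degenerate = _paired_wilcoxon(x[ok], y[ok])
        results.append(TestResult(
            method="wilcoxon_signed_rank", statistic=stat, df=(g1, g2), p=p,
            threshold=threshold, significant=p < threshold,
            degenerate=degenerate,
        ))
    return results


def pairwise_te_correlation(
    te: TEMatrix, alpha: float = 0.05, pairs: Optional[Sequence[tuple[str, str]]] = None
) -> list[TestResult]:
    """Spearman rank correlations of TE between gene pairs (mid-rank ties)."""
    df = te.to_frame()
    if pairs is None:
        pairs = list(combinations(te.genes, 2))
    threshold = bonferroni_threshold(alpha, len(pairs))
    results = []
    for g1, g2 in pairs:
        x, y = df.loc[g1].to_numpy(), df.loc[g2].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 5:
            raise ValueError(f"fewer than 5 complete pairs for {g1} vs {g2}")
        if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            results.append(TestResult(
                method="spearman", statistic=np.nan, df=(g1, g2), p=np.nan,
                threshold=threshold, significant=False, degenerate=True))
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        results.append(TestResult(
            method="spearman", statistic=float(rho), df=(g1, g2), p=float(p),
            threshold=threshold, significant=p < threshold, degenerate=False))
    return results
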