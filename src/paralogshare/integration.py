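"""Protein-output shares: expression x translational efficiency.

Because the paralogs encode an identical protein, the contribution of
gene i to the shared protein pool in a sample is proportional to its
PDUI-adjusted per-nt mRNA level times its (median) translational
efficiency; closing these products to sum 1 gives the translated share.
Under the assumption that both alleles of a gene are expressed and
translated equally, a heterozygous missense carrier produces mutant
protein amounting to half that gene's translated share.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TranslationShare:
    sample_id: str
    parts: list[str]
    translated_fraction: np.ndarray  # sums to 1

    def __post_init__(self) -> None:
        self.translated_fraction = np.asarray(self.translated_fraction, dtype=float)
        if abs(self.translated_fraction.sum() - 1.0) > 1e-9:
            raise ValueError("translated fractions must sum to 1")

    @property
    def mutant_dosage_fraction(self) -> np.ndarray:
        """Per-gene heterozygous mutant protein fraction (share / 2)."""
        return self.translated_fraction / 2.0


def translated_share(
    pdui_adjusted: dict[str, float],
    median_te: dict[str, float],
    sample_id: str = "",
) -> TranslationShare:
    """Close pdui_adjusted_i x median_te_i over the gene family to sum 1.

    ``median_te`` may cover more genes than the family; every family gene
    must have a TE.
    """
    missing = set(pdui_adjusted) - set(median_te)
    if missing:
        raise ValueError(f"no median TE for genes: {sorted(missing)}")
    parts = list(pdui_adjusted)
    te = np.array([median_te[g] for g in parts], dtype=float)
    if np.any(te <= 0):
        raise ValueError("median TE must be strictly positive for all genes")
    expr = np.array([pdui_adjusted[g] for g in parts], dtype=float)
    product = expr * te
    total = product.sum()
    if total <= 0:
        raise ValueError(f"sample {sample_id}: no expression, share undefined")
    return TranslationShare(sample_id, parts, product / total)


def translated_share_table(
    norm: pd.DataFrame, median_te: dict[str, float]
) -> pd.DataFrame:
    """Per-sample translated shares from long-format normalized expression.

    ``norm`` is the output of :func:`paralogshare.expression.normalize_matrix`.
    Returns a long frame: sample_id, gene_id, translated_fraction,
    translated_percent, mutant_dosage_percent.
    """
    rows = []
    for sample, sub in norm.groupby("sample_id", sort=True):
        adj = dict(zip(sub["gene_id"], sub["pdui_adjusted"]))
        share = translated_share(adj, median_te, sample_id=str(sample))
        for gene, frac in zip(share.parts, share.translated_fraction):
            rows.append({
                "sample_id": sample, "gene_id": gene,
                "translated_fraction": frac,
                "translated_percent": 100.0 * frac,
                "mutant_dosage_percent": 50.0 * frac,
            })
    return pd.DataFrame(rows)


def summarize_shares(shares: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mean and range of translated percent plus rounded dosage."""
    out = shares.groupby("gene_id", sort=True)["translated_percent"].agg(
        mean="mean", min="min", max="max")
    out["mutant_dosage_percent"] = out["mean"] / 2.0
    # reported dosages are rounded to the nearest integer percent
    out["mutant_dosage_rounded"] = out["mutant_dosage_percent"].round().astype(int)
    return out.reset_index()


def mutant_dosage(share: TranslationShare, target_gene: str) -> float:
    """Heterozygous mutant protein fraction for one gene of the family."""
    if target_gene not in share.parts:
        raise KeyError(f"unknown gene {target_gene!r}")
    return float(share.translated_fraction[share.parts.index(target_gene)] / 2.0)
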