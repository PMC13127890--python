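"""Gene-length and APA-aware expression normalization.

Three quantities, all within-sample:

* counts per nt          = counts / (l_5utr + l_cds + l_3utr)
* PDUI-adjusted c.p.nt   = counts / (l_5utr + l_cds + l_3utr * PDUI)
* percentage expressed   = counts_i / sum_j counts_j * 100

The PDUI adjustment replaces the annotated 3'-UTR length with the length
actually used: when only a fraction PDUI of transcripts carries the full
3'-UTR, dividing by the full length underestimates the expression of
long-UTR genes.  At PDUI = 1 the two measures coincide exactly.

Fractions are carried internally on [0, 1]; multiply by 100 only when
reporting percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, TranscriptModel, ValidationError


@dataclass
class Composition:
    """Per-sample relative abundances of a gene family, summing to 1."""

    sample_id: str
    parts: list[str]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < 0):
            raise ValidationError("negative composition fraction")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValidationError("composition does not sum to 1")

    @property
    def percentages(self) -> np.ndarray:
        return self.fractions * 100.0


def counts_per_nt(counts: float, model: TranscriptModel) -> float:
    """Read counts divided by total transcript length (5'-UTR + CDS + 3'-UTR)."""
    length = model.total_length
    if length <= 0:
        raise ValueError(f"{model.gene_id}: non-positive total length")
    return counts / length


def pdui_adjusted_counts_per_nt(
    counts: float, model: TranscriptModel, pdui: float
) -> float:
    """Counts per nt with the 3'-UTR length scaled by its usage.

    Denominator is ``l_5utr + l_cds + l_3utr * pdui``; at ``pdui=1`` this
    is bit-for-bit identical to :func:`counts_per_nt`.
    """
    if not (0.0 <= pdui <= 1.0):
        raise ValueError(f"PDUI must be in [0, 1], got {pdui}")
    return counts / (model.l_5utr + model.l_cds + model.l_3utr * pdui)


def percentage_expressed(
    values: dict[str, float], sample_id: str = ""
) -> Composition:
    """Close per-gene normalized values to a within-sample composition."""
    if len(values) < 2:
        raise ValueError("need at least 2 genes to form a composition")
    parts = list(values)
    arr = np.array([values[g] for g in parts], dtype=float)
    total = arr.sum()
    if total <= 0:
        import logging
        logging.getLogger("paralogshare").warning(
            "all-zero sample %s: composition undefined", sample_id)
        return None  # type: ignore[return-value]
    return Composition(sample_id, parts, arr / total)


def normalize_matrix(
    rna: CountMatrix,
    models: list[TranscriptModel],
    pdui: pd.DataFrame | None = None,
    missing_pdui: str = "error",
) -> pd.DataFrame:
    """Long-format per-gene-per-sample normalized expression.

    ``pdui`` is a long frame with columns gene_id, sample_id, pdui (as
    produced by :mod:`paralogshare.apa_pdui`); ``missing_pdui`` controls
    the fallback when a gene-sample PDUI is absent or NaN: ``"error"``
    (default — silent imputation would bias the composition toward
    long-UTR genes), ``"use-full-utr"`` (PDUI = 1), or ``"drop-sample"``
    (exclude samples lacking a PDUI for any gene).

    Returns columns: sample_id, gene_id, counts, counts_per_nt,
    pdui_adjusted, fraction, percent (fractions from the PDUI-adjusted
    measure).
    """
    if missing_pdui not in ("error", "use-full-utr", "drop-sample"):
        raise ValueError(f"unknown missing_pdui policy {missing_pdui!r}")
    by_gene = {m.gene_id: m for m in models}
    missing_models = set(rna.genes) - set(by_gene)
    if missing_models:
        raise ValidationError(f"no transcript model for genes {sorted(missing_models)}")
    lookup: dict[tuple[str, str], float] = {}
    if pdui is not None:
        for r in pdui.itertuples():
            lookup[(str(r.gene_id), str(r.sample_id))] = (
                float(r.pdui) if pd.notna(r.pdui) else np.nan)

    rows = []
    counts = rna.to_frame()
    dropped = []
    for sample in rna.samples:
        per_gene_adj: dict[str, float] = {}
        sample_rows = []
        skip = False
        for gene in rna.genes:
            m = by_gene[gene]
            c = float(counts.at[gene, sample])
            p = lookup.get((gene, sample), np.nan) if pdui is not None else 1.0
            if pdui is not None and not np.isfinite(p):
                if missing_pdui == "error":
                    raise ValidationError(
                        f"missing PDUI for gene {gene}, sample {sample}; "
                        "pass missing_pdui='use-full-utr' to assume full 3'-UTR usage")
                if missing_pdui == "drop-sample":
                    skip = True
                    break
                p = 1.0
            cpn = counts_per_nt(c, m)
            adj = pdui_adjusted_counts_per_nt(c, m, p)
            per_gene_adj[gene] = adj
            sample_rows.append({
                "sample_id": sample, "gene_id": gene, "counts": c,
                "counts_per_nt": cpn, "pdui_adjusted": adj, "pdui": p,
            })
        if skip:
            dropped.append(sample)
            continue
        comp = percentage_expressed(per_gene_adj, sample)
        for row in sample_rows:
            if comp is None:
                row["fraction"] = np.nan
            else:
                row["fraction"] = comp.fractions[comp.parts.index(row["gene_id"])]
            row["percent"] = row["fraction"] * 100.0
        rows.extend(sample_rows)
    if dropped:
        import logging
        logging.getLogger("paralogshare").warning(
            "dropped %d samples lacking PDUI estimates: %s",
            len(dropped), dropped[:5])
    return pd.DataFrame(rows)


def composition_matrix(norm: pd.DataFrame, column: str = "fraction") -> pd.DataFrame:
    """Pivot long-format normalized expression to samples x genes fractions."""
    wide = norm.pivot(index="sample_id", columns="gene_id", values=column)
    return wide.dropna()
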