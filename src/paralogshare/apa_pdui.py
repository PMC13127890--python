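"""Distal poly(A)-site usage (PDUI) from 3'-UTR coverage.

Alternative polyadenylation produces, per gene, a mixture of a short
isoform (ending at a proximal poly(A) site inside the 3'-UTR) and a long
isoform (full-length 3'-UTR).  Expected per-base coverage is then a
two-level step function: ``w_short + w_long`` upstream of the proximal
site and ``w_long`` downstream of it.  PDUI — the fraction of transcripts
using the distal site — is ``w_long / (w_long + w_short)``.

This module fits that two-segment model by least squares over a breakpoint
grid.  For a candidate breakpoint the segment means are the unconstrained
optimum; the physical constraint ``w_short >= 0`` (coverage cannot rise
after the proximal site) is enforced by collapsing to a single flat level
whenever the downstream mean exceeds the upstream one.  Ties in residual
sum of squares resolve to the smallest breakpoint.  A pooled multi-sample
mode picks one shared breakpoint per gene by minimising the summed RSS
across samples, then refits per-sample weights at that breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import CoverageTrack

#: default minimum mean depth for a usable track
DEFAULT_MIN_COVERAGE = 10.0
#: default minimum segment length (nt) on each side of a breakpoint
DEFAULT_MIN_SEGMENT = 50


@dataclass
class PDUIEstimate:
    gene_id: str
    sample_id: str
    pdui: Optional[float]
    breakpoint: Optional[int]
    w_long: float
    w_short: float
    qc_flag: str  # ok | low_coverage | degenerate


def _candidate_rss(depth: np.ndarray, min_segment: int) -> tuple[np.ndarray, np.ndarray]:
    """RSS of the constrained two-segment fit at every candidate breakpoint.

    Returns (breakpoints, rss), vectorised via prefix sums.  Candidates are
    b in [min_segment, L - min_segment]; segment 1 is [0, b), segment 2 [b, L).
    """
    L = len(depth)
    b = np.arange(min_segment, L - min_segment + 1)
    cs = np.concatenate([[0.0], np.cumsum(depth)])
    cs2 = np.concatenate([[0.0], np.cumsum(depth ** 2)])
    n1 = b.astype(float)
    n2 = L - n1
    s1, s2 = cs[b], cs[L] - cs[b]
    m1, m2 = s1 / n1, s2 / n2
    total_sq = cs2[L]
    # unconstrained: per-segment means
    rss = total_sq - n1 * m1 ** 2 - n2 * m2 ** 2
    # constraint m2 <= m1 violated -> single flat level (w_short clipped at 0)
    flat_rss = total_sq - L * (cs[L] / L) ** 2
    rising = m2 > m1
    rss = np.where(rising, flat_rss, rss)
    return b, rss


def _fit_at_breakpoint(depth: np.ndarray, b: int) -> tuple[float, float]:
    """(w_short, w_long) of the constrained fit at a fixed breakpoint."""
    m1 = float(depth[:b].mean())
    m2 = float(depth[b:].mean())
    if m2 > m1:  # coverage rises: clip w_short at 0, single level
        return 0.0, float(depth.mean())
    return m1 - m2, m2


def estimate_pdui(
    track: CoverageTrack,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> PDUIEstimate:
    """Fit the two-isoform model to one track and report PDUI.

    Tracks with mean depth below ``min_coverage`` (including all-zero
    tracks) are reported as missing with ``qc_flag='low_coverage'``.
    """
    depth = track.depth
    if len(depth) < 2 * min_segment:
        raise ValueError(
            f"track for {track.gene_id} has length {len(depth)} "
            f"< 2 x min_segment ({min_segment})"
        )
    if depth.mean() < min_coverage:
        return PDUIEstimate(track.gene_id, track.sample_id, None, None,
                            0.0, 0.0, "low_coverage")
    bks, rss = _candidate_rss(depth, min_segment)
    best = int(bks[np.argmin(rss)])  # argmin returns first => smallest b on ties
    w_short, w_long = _fit_at_breakpoint(depth, best)
    return _assemble(track, best, w_short, w_long)


def _assemble(track: CoverageTrack, b: int, w_short: float, w_long: float) -> PDUIEstimate:
    total = w_short + w_long
    if total <= 0:
        return PDUIEstimate(track.gene_id, track.sample_id, None, None,
                            0.0, 0.0, "degenerate")
    pdui = w_long / total
    return PDUIEstimate(track.gene_id, track.sample_id, float(pdui), b,
                        float(w_long), float(w_short), "ok")


def estimate_pdui_multisample(
    tracks: Sequence[CoverageTrack],
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> list[PDUIEstimate]:
    """One shared breakpoint per gene across samples; per-sample weights.

    The shared breakpoint minimises the pooled (summed) RSS over all
    usable tracks.  Low-coverage tracks are excluded from the pooling and
    reported missing.
    """
    if not tracks:
        raise ValueError("need at least one track")
    lengths = {len(t.depth) for t in tracks}
    if len(lengths) != 1:
        raise ValueError("all tracks for a gene must share the 3'-UTR length")
    usable = [t for t in tracks if t.depth.mean() >= min_coverage]
    out: list[PDUIEstimate] = []
    if not usable:
        return [PDUIEstimate(t.gene_id, t.sample_id, None, None, 0.0, 0.0,
                             "low_coverage") for t in tracks]
    pooled = None
    for t in usable:
        bks, rss = _candidate_rss(t.depth, min_segment)
        pooled = rss if pooled is None else pooled + rss
    best = int(bks[np.argmin(pooled)])
    for t in tracks:
        if t.depth.mean() < min_coverage:
            out.append(PDUIEstimate(t.gene_id, t.sample_id, None, None,
                                    0.0, 0.0, "low_coverage"))
        else:
            w_short, w_long = _fit_at_breakpoint(t.depth, best)
            out.append(_assemble(t, best, w_short, w_long))
    return out


def estimates_to_frame(estimates: Sequence[PDUIEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": e.gene_id, "sample_id": e.sample_id, "pdui": e.pdui,
        "breakpoint": e.breakpoint, "w_long": e.w_long, "w_short": e.w_short,
        "qc_flag": e.qc_flag,
    } for e in estimates])


def summarize_pdui(
    estimates: Sequence[PDUIEstimate],
    group: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Per-gene (optionally per-group) median and range of PDUI.

    ``group`` maps sample_id to a grouping label (e.g. tissue); missing
    estimates are ignored.  Genes with no usable estimate produce an empty
    summary row carrying NaNs.
    """
    df = estimates_to_frame(estimates)
    if group is not None:
        df["group"] = df["sample_id"].map(group)
        keys = ["gene_id", "group"]
    else:
        keys = ["gene_id"]
    rows = []
    for key, sub in df.groupby(keys, sort=True):
        vals = sub["pdui"].dropna()
        key = key if isinstance(key, tuple) else (key,)
        row = dict(zip(keys, key))
        if vals.empty:
            import logging
            logging.getLogger("paralogshare").warning(
                "no usable PDUI estimates for %s", key)
            row.update({"n": 0, "median": np.nan, "min": np.nan, "max": np.nan})
        else:
            row.update({"n": int(len(vals)), "median": float(vals.median()),
                        "min": float(vals.min()), "max": float(vals.max())})
        rows.append(row)
    return pd.DataFrame(rows)
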