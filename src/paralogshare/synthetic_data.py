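"""Synthetic datasets with the statistical structure the pipeline assumes.

The generator emulates the two expression resources the analysis is built
on, for a family of paralogs encoding one protein:

* a bulk RNA-seq resource (GTEx-like): whole-transcript read counts whose
  expectation embeds the effective transcript length
  ``l_5utr + l_cds + PDUI x l_3utr``, plus per-base 3'-UTR coverage that
  steps down at the proximal poly(A) site — so the PDUI estimator and the
  PDUI-adjusted normalization are exact inverses of the construction in
  expectation;
* a paired RNA/ribosome-profiling resource (cardiac-translatome-like):
  CDS-mapped counts for both assays, with the ribo expectation scaled by
  the gene's translational efficiency, so the ribo/RNA ratio recovers TE.

Defaults are the three calmodulin genes with their annotated lengths
(3'-UTRs 3544/694/1640 nt, CDS 450 nt), left-ventricle PDUI medians
(0.39/0.81/0.64), mean expression shares (36.8/41.9/21.3%) and median
TEs (3.01/2.59/1.26).  Expression shares are drawn logistic-normally
around the mean composition; counts are Poisson (negative binomial
optional); everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .comp_stats import ilr_matrix, ilr_basis
from .io_formats import (
    CohortTable,
    ConstraintRecord,
    CountMatrix,
    CoverageTrack,
    TranscriptModel,
    write_annotation,
    write_bedgraph_coverage,
    write_count_matrix,
)


@dataclass(frozen=True)
class GeneSpec:
    gene_id: str
    l_5utr: int
    l_cds: int
    l_3utr: int
    proximal_site: int  # offset of the proximal poly(A) site into the 3'-UTR

    def __post_init__(self) -> None:
        if not 0 < self.proximal_site < self.l_3utr:
            raise ValueError(
                f"{self.gene_id}: proximal_site must lie strictly inside "
                f"(0, {self.l_3utr})")


def _default_genes() -> list[GeneSpec]:
    # proximal sites at ~30% of the 3'-UTR; CALM2's 5'-UTR (158 nt) and
    # CALM1's (248 nt) follow from the annotated total lengths 1302/4242
    return [
        GeneSpec("CALM1", 248, 450, 3544, 1063),
        GeneSpec("CALM2", 158, 450, 694, 208),
        GeneSpec("CALM3", 131, 450, 1640, 492),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 80
    genes: list[GeneSpec] = field(default_factory=_default_genes)
    #: per-gene mean distal-site usage and its between-sample sd, on (0, 1]
    true_pdui_mean: tuple[float, ...] = (0.39, 0.81, 0.64)
    true_pdui_sd: tuple[float, ...] = (0.08, 0.08, 0.08)
    #: mean expression composition (sums to 1)
    true_expression_share: tuple[float, ...] = (0.368, 0.419, 0.213)
    #: logistic-normal dispersion of the shares, on the ILR scale
    share_dispersion: float = 0.15
    #: per-gene translational efficiency
    true_te: tuple[float, ...] = (3.01, 2.59, 1.26)
    #: per-sample sequencing-depth factors; None -> lognormal(0, 0.25)
    size_factors: Optional[np.ndarray] = None
    #: mean coverage per expressed transcript unit
    depth: float = 100.0
    #: background genes added to the paired RNA/ribo (CDS) matrices so that
    #: joint size-factor estimation is anchored by a transcriptome-like
    #: majority with TE = 1, as in genome-wide normalization; the family
    #: genes' TE is then identified on an absolute scale
    n_background: int = 200
    noise: str = "poisson"  # poisson | negative_binomial | none (zero-variance limit)
    nb_dispersion: float = 0.05  # var = mu + phi mu^2
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.genes)
        for name in ("true_pdui_mean", "true_pdui_sd", "true_te",
                     "true_expression_share"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per gene")
        if abs(sum(self.true_expression_share) - 1.0) > 1e-12:
            raise ValueError("true_expression_share must sum to 1")
        if self.depth <= 0 or any(t <= 0 for t in self.true_te):
            raise ValueError("depth and TE must be positive")
        if any(not 0 < m <= 1 for m in self.true_pdui_mean):
            raise ValueError("PDUI means must be in (0, 1]")
        if self.noise not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class TruthBundle:
    """Generating parameters stored alongside every simulated dataset."""

    pdui: pd.DataFrame          # samples x genes, true per-sample PDUI
    composition: pd.DataFrame   # samples x genes, true shares (rows sum to 1)
    te: pd.Series               # per-gene true TE
    size_factors: pd.Series     # per-sample true depth factor


@dataclass
class SimulatedDataset:
    annotation: list[TranscriptModel]
    coverage: list[CoverageTrack]
    rna: CountMatrix       # whole-transcript counts (expression/PDUI pathway)
    rna_cds: CountMatrix   # CDS-mapped counts paired with ribo (TE pathway)
    ribo: CountMatrix
    truth: TruthBundle


def _noise(rng: np.random.Generator, mu: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    if cfg.noise == "none":  # zero-variance limit: counts equal expectations
        return np.asarray(mu, dtype=float).copy()
    if cfg.noise == "poisson":
        return rng.poisson(mu).astype(float)
    # NB parameterized by mean and dispersion phi: var = mu + phi mu^2
    phi = cfg.nb_dispersion
    if phi <= 0:
        return rng.poisson(mu).astype(float)
    r = 1.0 / phi
    p = r / (r + mu)
    return rng.negative_binomial(r, p).astype(float)


def _draw_compositions(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    """Logistic-normal draws centred (on the ILR scale) at the mean share."""
    mean = np.asarray(cfg.true_expression_share, dtype=float)
    center = ilr_matrix(mean[None, :])[0]
    coords = rng.normal(center, cfg.share_dispersion,
                        size=(cfg.n_samples, len(mean) - 1))
    logx = coords @ ilr_basis(len(mean)).T
    x = np.exp(logx)
    return x / x.sum(axis=1, keepdims=True)


def _draw_pdui(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    mean = np.asarray(cfg.true_pdui_mean)
    sd = np.asarray(cfg.true_pdui_sd)
    if np.all(sd == 0):
        return np.tile(mean, (cfg.n_samples, 1))
    draws = rng.normal(mean, sd, size=(cfg.n_samples, len(mean)))
    return np.clip(draws, 0.02, 1.0)


def _annotation(cfg: SimulationConfig) -> list[TranscriptModel]:
    models, cursor = [], 1000
    for g in cfg.genes:
        models.append(TranscriptModel(
            gene_id=g.gene_id, transcript_id=f"{g.gene_id}-tx",
            l_5utr=g.l_5utr, l_cds=g.l_cds, l_3utr=g.l_3utr,
            chrom=f"chr_{g.gene_id}", utr3_start=cursor,
            utr3_end=cursor + g.l_3utr, strand="+"))
        cursor += g.l_3utr + 10_000
    return models


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Generate one full synthetic dataset plus its generating truth.

    Expectations (sample s, gene g, size factor f_s, depth d, share w,
    PDUI u, TE t):

    * whole-transcript RNA count: f_s d w_gs (l5 + lcds + u_gs l3)
    * CDS RNA count:              f_s d w_gs lcds
    * ribo count:                 f_s d w_gs lcds t_g
    * 3'-UTR coverage per base:   f_s d w_gs before the proximal site,
                                  f_s d w_gs u_gs after it
    """
    rng = np.random.default_rng(cfg.seed)
    k = len(cfg.genes)
    samples = [f"S{i:03d}" for i in range(cfg.n_samples)]
    gene_ids = [g.gene_id for g in cfg.genes]

    sf = (np.asarray(cfg.size_factors, dtype=float)
          if cfg.size_factors is not None
          else np.exp(rng.normal(0.0, 0.25, size=cfg.n_samples)))
    if len(sf) != cfg.n_samples or np.any(sf <= 0):
        raise ValueError("size_factors must be positive, one per sample")
    # ribo libraries get their own depth factors
    sf_ribo = (sf * np.exp(rng.normal(0.0, 0.25, size=cfg.n_samples)))

    shares = _draw_compositions(rng, cfg)        # n x k
    pdui = _draw_pdui(rng, cfg)                  # n x k
    te = np.asarray(cfg.true_te, dtype=float)

    l5 = np.array([g.l_5utr for g in cfg.genes], dtype=float)
    lcds = np.array([g.l_cds for g in cfg.genes], dtype=float)
    l3 = np.array([g.l_3utr for g in cfg.genes], dtype=float)

    eff_len = l5[None, :] + lcds[None, :] + pdui * l3[None, :]        # n x k
    base = sf[:, None] * cfg.depth * shares                           # n x k
    mu_rna = base * eff_len
    mu_cds = base * lcds[None, :]
    mu_ribo = sf_ribo[:, None] * cfg.depth * shares * lcds[None, :] * te[None, :]

    rna = CountMatrix(gene_ids, samples, _noise(rng, mu_rna, cfg).T, "rna")

    # paired matrices carry background genes (TE = 1) with per-gene levels
    # constant across samples, so median-of-ratios sees a TE-neutral majority
    bg_ids = [f"BG{i:03d}" for i in range(cfg.n_background)]
    bg_level = np.exp(rng.normal(np.log(5000.0), 1.0, size=cfg.n_background))
    mu_bg_rna = sf[:, None] * bg_level[None, :]                       # n x B
    mu_bg_ribo = sf_ribo[:, None] * bg_level[None, :]
    cds_counts = np.vstack([_noise(rng, mu_cds, cfg).T,
                            _noise(rng, mu_bg_rna, cfg).T])
    ribo_counts = np.vstack([_noise(rng, mu_ribo, cfg).T,
                             _noise(rng, mu_bg_ribo, cfg).T])
    rna_cds = CountMatrix(gene_ids + bg_ids, samples, cds_counts, "rna")
    ribo = CountMatrix(gene_ids + bg_ids, samples, ribo_counts, "ribo")

    coverage = []
    for si, sample in enumerate(samples):
        for gi, g in enumerate(cfg.genes):
            d_total = base[si, gi]
            mu_cov = np.full(g.l_3utr, d_total)
            mu_cov[g.proximal_site:] = d_total * pdui[si, gi]
            coverage.append(CoverageTrack(
                g.gene_id, sample, _noise(rng, mu_cov, cfg)))

    truth = TruthBundle(
        pdui=pd.DataFrame(pdui, index=samples, columns=gene_ids),
        composition=pd.DataFrame(shares, index=samples, columns=gene_ids),
        te=pd.Series(te, index=gene_ids, name="true_te"),
        size_factors=pd.Series(sf, index=samples, name="size_factor"),
    )
    return SimulatedDataset(_annotation(cfg), coverage, rna, rna_cds, ribo, truth)


def expected_counts(cfg: SimulationConfig, truth: TruthBundle) -> pd.DataFrame:
    """Noise-free whole-transcript RNA expectations for the given truth."""
    l5 = np.array([g.l_5utr for g in cfg.genes], dtype=float)
    lcds = np.array([g.l_cds for g in cfg.genes], dtype=float)
    l3 = np.array([g.l_3utr for g in cfg.genes], dtype=float)
    eff = l5 + lcds + truth.pdui.to_numpy() * l3
    mu = truth.size_factors.to_numpy()[:, None] * cfg.depth \
        * truth.composition.to_numpy() * eff
    return pd.DataFrame(mu, index=truth.pdui.index, columns=truth.pdui.columns)


def simulate_cohort(
    n_per_gene: Sequence[int],
    event_prob: Sequence[float],
    seed: int,
    genes: Optional[Sequence[str]] = None,
    phenotype_label: str = "all",
) -> CohortTable:
    """Binomial registry-style cohort: carriers with/without an event."""
    if len(n_per_gene) != len(event_prob):
        raise ValueError("n_per_gene and event_prob must align")
    if any(not 0 <= p <= 1 for p in event_prob):
        raise ValueError("event probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else [
        f"GENE{i+1}" for i in range(len(n_per_gene))]
    with_event = [int(rng.binomial(n, p)) for n, p in zip(n_per_gene, event_prob)]
    df = pd.DataFrame({
        "gene_id": genes,
        "with_event": with_event,
        "without_event": [n - w for n, w in zip(n_per_gene, with_event)],
    })
    return CohortTable(df, phenotype_label=phenotype_label)


def simulate_constraint(
    expected: Sequence[float],
    true_oe: Sequence[float],
    seed: int,
    genes: Optional[Sequence[str]] = None,
    variant_class: str = "missense",
) -> list[ConstraintRecord]:
    """Poisson observed counts around true_oe x expected per gene."""
    if len(expected) != len(true_oe):
        raise ValueError("expected and true_oe must align")
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else [
        f"GENE{i+1}" for i in range(len(expected))]
    return [
        ConstraintRecord(g, variant_class, int(rng.poisson(oe * e)), float(e))
        for g, e, oe in zip(genes, expected, true_oe)
    ]


def write_dataset(ds: SimulatedDataset, out_dir: str | Path) -> None:
    """Write a simulated dataset as plain-text files under out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation(ds.annotation, out / "annotation.tsv")
    write_count_matrix(ds.rna, out / "rna_counts.tsv")
    write_count_matrix(ds.rna_cds, out / "rna_cds_counts.tsv")
    write_count_matrix(ds.ribo, out / "ribo_counts.tsv")
    cov_dir = out / "coverage"
    cov_dir.mkdir(exist_ok=True)
    by_sample: dict[str, list[CoverageTrack]] = {}
    for t in ds.coverage:
        by_sample.setdefault(t.sample_id, []).append(t)
    for sample, tracks in by_sample.items():
        write_bedgraph_coverage(tracks, ds.annotation,
                                cov_dir / f"{sample}.bedgraph")
    ds.truth.pdui.to_csv(out / "truth_pdui.tsv", sep="\t", index_label="sample_id")
    ds.truth.composition.to_csv(out / "truth_composition.tsv", sep="\t",
                                index_label="sample_id")
    ds.truth.te.to_frame().to_csv(out / "truth_te.tsv", sep="\t",
                                  index_label="gene_id")
    ds.truth.size_factors.to_frame().to_csv(out / "truth_size_factors.tsv",
                                            sep="\t", index_label="sample_id")
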