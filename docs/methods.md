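# Methods

## The problem

`CALM1`, `CALM2` and `CALM3` encode an identical calmodulin protein, so a
heterozygous missense variant's dosage — the fraction of the total
calmodulin pool that carries the mutation — depends on the host gene's
share of transcription *and* translation, neither of which can be read
off a protein assay. The pipeline estimates that share from bulk
RNA-seq coverage and counts plus paired ribosome profiling, and relates
it to gene-specific variant statistics (population constraint, clinical
event rates). Everything generalizes to any paralog family with a shared
protein product; the calmodulin genes are the defaults throughout.

## PDUI: the two-isoform breakpoint model

Alternative polyadenylation (APA) mixes, per gene, a short isoform ending
at a proximal poly(A) site inside the 3′-UTR with a long, full-length
isoform. Expected per-base coverage along the 3′-UTR is then a two-level
step: `w_short + w_long` upstream of the proximal site and `w_long`
downstream. For every candidate breakpoint `b` in
`[min_segment, L − min_segment]` the model fits the two levels by least
squares — segment means, with the physical constraint `w_short ≥ 0`
(coverage cannot rise at a poly(A) site) enforced by collapsing to one
flat level when the downstream mean exceeds the upstream one — and keeps
the `b` minimizing the residual sum of squares (ties → smallest `b`, for
determinism). PDUI = `w_long / (w_long + w_short)` ∈ [0, 1]; the
estimate is scale-free in depth. This is a deliberately minimal mean-shift
model: it captures the PDUI quantity without multi-breakpoint APA,
de-novo site discovery, or coverage-bias regression.

Multi-sample mode pools the per-breakpoint RSS across a gene's samples,
picks one shared breakpoint, and refits per-sample weights — the poly(A)
site is a property of the gene, the usage a property of the sample. Both
per-sample and pooled modes are exposed because either convention is
defensible.

Tunables: `min_segment` (default 50 nt) keeps degenerate one-sided fits
off the grid; `min_coverage` (default 10× mean per-base depth) flags
tracks too shallow to fit, reported as missing with `qc_flag =
low_coverage` rather than imputed. Both are module defaults chosen for
robustness, not empirical estimates.

## Normalization and compositions

Within-sample comparisons among family members use counts per nucleotide
of *effective* transcript: `counts / (l5′UTR + lCDS + l3′UTR × PDUI)`.
At PDUI = 1 this equals plain counts-per-nt bit for bit (same float
denominator). Missing PDUIs are never silently imputed — the default
errors, with explicit `use-full-utr` (PDUI = 1) and `drop-sample`
policies — because imputation of full usage systematically deflates
long-UTR genes, the very artefact the adjustment corrects.

Per-sample fractions are carried on [0, 1] and multiplied by 100 only at
reporting. Because the fractions sum to 1 they are compositional: tests
run on isometric log-ratio (ILR) coordinates under the fixed
sequential-binary orthonormal basis (`coords_i = √(i/(i+1)) ·
ln(gmean(x₁..x_i)/x_{i+1})`, equal to `Vᵀ log x` for the recorded
contrast matrix `V`). The uniform composition maps to the origin, so the
one-sample Hotelling's T² — `T² = n (x̄−μ₀)ᵀ S⁻¹ (x̄−μ₀)`, referred to
`F(p, n−p)` via `F = (n−p)/(p(n−1)) T²` — tests departure from equal
sharing with a basis-invariant p-value (verified by part-permutation
tests). Post-hoc localization uses one-sample t-tests on per-sample
differences of fractions (a paired t-test); an alternative on pairwise
log-ratio coordinates is available via `on="ilr"` since the choice of
post-hoc space is genuinely open. Zero parts abort the ILR with a
pointer to the opt-in multiplicative zero-replacement.

Multiple testing everywhere follows the divide-by-n rule: significant iff
p < α / n_tests, with n_tests explicit in the result objects.

## Translational efficiency

RNA-seq and ribosome-profiling columns enter one joint matrix for
median-of-ratios size factors (per column: median over genes positive in
every column of count / row geometric mean; the median is taken in ratio
space, where it differs from `exp(median(log ratio))` for even reference
counts). Joint — not per-assay — normalization is what makes the
ribo/RNA ratio comparable across assays. TE = `(ribo/sf) / (rna/sf)` per
gene and sample, with no length adjustment because the inputs are
CDS-mapped and the family's CDS lengths are identical; TE is missing
(never infinite) where the RNA count is zero, and per-gene medians skip
missing values. Pairwise comparisons use the two-sided Wilcoxon
signed-rank test (exact null for ≤ 25 tie-free pairs, normal
approximation otherwise; zero differences dropped per the standard
signed-rank convention) and Spearman correlations with mid-rank ties.

## Integration and mutant dosage

Per sample, translated share_i ∝ PDUI-adjusted counts-per-nt_i × median
TE_i, closed to sum 1 — invariant to rescaling all TEs, and reducing bit
for bit to the expression composition when TEs are equal. Shares are
computed per sample and then summarized (mean, range), with a pooled
mode available. Assuming both alleles of a gene are expressed and
translated equally, a heterozygous carrier's mutant dosage is the share
halved; reported integers use nearest-integer rounding.

## Cohort and constraint statistics

Registry-style r×2 tables (carriers with/without a cardiac event per
gene) are tested with Pearson chi-squared without continuity correction
(the correction applies only to 2×2 tables), df = r−1, and with an exact
Fisher-style test that fully enumerates margin-fixed tables (multivariate
hypergeometric probabilities; p sums tables no more probable than the
observed one, with a 1e-7 relative tie tolerance; enumeration is refused
above 200 subjects in favour of chi-squared). Reported integer
percentages are derived by half-up rounding of the one-decimal display
value (88.46 → 88.5 → 89), matching how such tables are conventionally
typeset; the exact percentage is always reported alongside.

Observed/expected constraint ratios get confidence intervals from the
normalized Poisson likelihood of the ratio on a grid (default r ∈ [0,10],
step 1e-3): the CI endpoints are the cumulative-likelihood crossings at
(1−level)/2 and 1−(1−level)/2; for observed = 0 the interval is
one-sided with upper bound at the `level + (1−level)/2` crossing, which
for a 90% CI reduces to the closed form `−ln(0.05)/expected`. Bounds are
reported to two decimals.

## The synthetic-data generator

The generator emulates the two expression resources the analysis needs,
at desk scale, with the truth stored beside every dataset so recovery is
checkable:

* **Whole-transcript RNA counts** (bulk, GTEx-like):
  `Poisson(sf_s · depth · share_gs · (l5′ + lCDS + PDUI_gs · l3′))` — the
  effective length embeds the per-sample PDUI, so PDUI-adjusted
  normalization inverts the construction exactly in expectation and
  share recovery is a sharp test.
* **3′-UTR coverage**: per-base Poisson around the two-level step
  (`d_total` before the proximal site, `d_total · PDUI` after).
* **Paired CDS-mapped RNA + ribo counts** (cardiac-translatome-like):
  `Poisson(sf · depth · share · lCDS)` and
  `Poisson(sf_ribo · depth · share · lCDS · TE)`. These matrices carry
  200 background genes with TE = 1 and sample-constant levels, because
  joint size factors are meaningful only when a transcriptome-like,
  TE-neutral majority anchors the per-column medians — with three genes
  alone the family's TE would be absorbed into the ribo size factors and
  only relative TEs would be identifiable.

Expression shares are logistic-normal around the mean composition
(normal on the ILR scale, dispersion 0.15 by default) — the standard
compositional distribution and the one the downstream ILR tests assume;
per-sample PDUIs are normal draws clipped to [0.02, 1]; size factors are
log-normal (σ = 0.25). Noise is Poisson by default, negative binomial
(`var = μ + φμ²`) or a zero-variance `none` switch optionally.
Everything is deterministic given the seed.

Defaults are the published study conditions: three genes with 3′-UTRs
3544/694/1640 nt, CDS 450 nt, PDUI means 0.39/0.81/0.64 with
between-sample sd 0.08, mean shares 36.8/41.9/21.3%, TEs 3.01/2.59/1.26,
80 samples, mean unit coverage 100. The 5′-UTR lengths are 248 nt
(CALM1) and 158 nt (CALM2), implied by the annotated total transcript
lengths 4242 and 1302 nt; CALM3's is not similarly pinned and is set to
131 nt, inside the annotated total-length range. Proximal poly(A) sites
default to ~30% of each 3′-UTR; real proximal-site positions are not part
of the study conditions, and the estimators are tested for recovering
PDUI regardless of where the site sits. Per-sample PDUI and TE
dispersions are free parameters — the source studies report summaries,
not variances — so they are set to modest values rather than calibrated.

What the generator does *not* emulate: genuine biological co-regulation
of TE across genes (simulated TEs are independent given the shares, so
TE correlations are null here), tissue structure, isoform mixtures
beyond one dominant transcript per gene, coverage GC/positional bias,
and overdispersion structure of real libraries. Passing recovery tests
therefore demonstrates that the estimators invert the stated generative
model, not that real GTEx-scale data would behave as cleanly.

In the registry cohort simulator, carriers with an event are binomial
draws per gene; in the constraint simulator, observed counts are
`Poisson(true_oe × expected)`. The analysis drivers use gnomAD-scale
expected counts (127/150/200 missense, ≈11 per gene for pLoF) with the
published o/e ratios as generating values; the real per-gene
observed/expected counts are not published in the tables reproduced
here, so printed ratios and CIs serve as simulation settings, and the
registry 3×2 table — which *is* published — ships verbatim as a fixture.

## Numerical choices and problem sizes

Internal coordinates are 0-based half-open, converted only at file
boundaries; coverage is stored 5′→3′ in transcript orientation so the
breakpoint model is strand-agnostic. Breakpoint fits are vectorized with
prefix sums (O(L) per track). RSS ties resolve to the smallest
breakpoint; `argmin` order makes this reproducible. The analysis
drivers, tests and the acceptance script run the study at 80 samples
(the size of the translatome cohort), 200 tracks for PDUI-recovery
checks, and 2000 replicates for calibration checks (Hotelling type-I
error, o/e CI coverage) — sizes at which all Monte-Carlo bands used in
the tests are comfortably inside binomial sampling error.

## Known limitations

The PDUI model assumes exactly two isoforms and one shared breakpoint;
genes with several proximal sites will fold their usage into a single
index. Joint size factors require at least one gene positive in every
column (no pseudocount is applied silently). The Fisher-style exact test
is exponential in the number of rows and is capped at 200 subjects. The
o/e confidence construction is a likelihood-interval convention, not a
frequentist guarantee, although its empirical coverage at gnomAD-scale
expected counts is ~90% in the tests.
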