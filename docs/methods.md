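# Methods

This note documents the statistical model, the defaults and the design
choices behind `episign`, in the spirit of a package vignette. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Data model and coordinates

Per-sample input is the Bismark coverage layout: one CpG per line with
1-based position (start == end), a percentage column and methylated /
unmethylated read counts. Counts are authoritative; beta is always
recomputed as m/(m+u), since the printed percentage is redundant and
rounding-lossy. BED inputs (islands, SNP mask, capture targets, genes)
are 0-based half-open and converted to the internal 1-based inclusive
convention on read. Strand is ignored: CpGs are keyed by (chrom, pos),
and dyad merging is assumed to have happened upstream in the methylation
extractor. The cohort matrix is the union of positions across samples;
a sample lacking a site holds NaN in both beta and coverage.

## QC

Four site rules run in a fixed order after per-cell coverage masking
(beta set missing where coverage < `min_coverage`, default 10X):

1. sex-chromosome sites (chrX/chrY; population sex-chromosome dosage is
   not a disease signal);
2. sites overlapping the SNP-mask intervals — operationalised as direct
   interval overlap, since any distance padding belongs to the mask's
   producer;
3. mean-coverage outliers: sites whose across-sample mean coverage
   exceeds the `coverage_outlier_quantile` (default 0.999) of the
   per-site mean-coverage distribution. The cutoff uses an attained
   order statistic (`method="higher"`), which keeps the rule stable
   under re-application at realistic matrix sizes;
4. sites missing in more than `max_missing_samples` samples (default 1),
   counted over the whole cohort in a single pass.

Counts removed per rule are reported and must reconcile exactly with the
input and retained totals.

## Per-site test

The default estimator is per-site OLS on the beta scale with a group
indicator and optional covariates, reading the two-sided t-test on the
group coefficient. With 2–6 cases against 64 controls this pools
residual variance across the whole cohort (residual df ≈ n − p), which
is what makes tiny case groups — including the k = 1 pseudo-case draws
of the null calibration — testable at all; it is also the closest fully
specified analogue of a limma-style moderated fit (no empirical-Bayes
shrinkage is applied; with ~60+ residual df the moderation would be
nearly inert anyway). The Welch unequal-variance test with Satterthwaite
df is provided as an alternative for balanced designs; at n = 4 its
3-ish degrees of freedom make p-values too coarse to survive
genome-wide FDR control, which is why it is not the default. Sites whose
missingness leaves the design rank-deficient are marked untestable.
Working on betas rather than M-values is a deliberate trade-off: effect
sizes stay interpretable as methylation differences (the >20% rule is
native to that scale) at the cost of some heteroscedasticity near the
boundaries.

Significance is the joint rule: Benjamini–Hochberg q < 0.05 (strict) and
|Δβ| > 0.20 (strict), with Δβ = mean(case) − mean(control). The joint
rule is strongly conservative under the null — the effect-size condition
alone sits several control-SDs out — which the subsampling calibration
quantifies.

## Regions

Context annotation uses the standard distances: island (inside a merged
island interval), shore (≤ 2 kb from an island edge), shelf (2–4 kb),
open sea (beyond). Islands take priority over shores over shelves.

DMB construction single-linkage-merges consecutive significant
non-island sites on a chromosome while inter-site gaps are ≤ 5 kb
(`dmb_gap_bp`), then keeps blocks spanning 5–200 kb. The 5 kb merge gap
is the one interpretive choice in the block definition; it is the only
reading consistent with the stated 5–200 kb block sizes, and it is
exposed as a parameter. At scoring time a DMB must also contain ≥ 3
capture target regions — a guard against blocks supported by a single
assay fragment; the target-count rule applies to DMBs only, islands
being externally defined.

Island candidates are islands containing ≥ 1 DMP; their combined
p-value uses **all tested member sites**, not only the significant ones,
so the region statistic reflects the whole island. Member p-values are
combined by Fisher's method (−2Σln p ~ χ²(2k)) by default. Brown's
extension is available for correlated neighbours: the same statistic is
referred to a scaled χ² whose moments are corrected by the pairwise
covariance of the −2 ln p terms, approximated from the control-beta
correlation r via the Kost–McDermott polynomial
3.263r + 0.710r² + 0.027r³. Fisher remains the default because region
p-values also pass through BH adjustment across the joint candidate
list (islands + DMBs), and the retained set additionally needs
|mean Δβ| > 0.20 — mean, not per-site quantile, as the simplest summary
of block-level effect.

## Episignature

Signature sites are the DMPs of the contrast. Control statistics use
controls only (mean, SD with n−1), and z = (β − μ)/σ for every sample;
σ = 0 sites yield missing z. GOM/LOM calls use |z| > 3 (two-sided
Gaussian tail ≈ 0.27% per site under the null, which the tests verify
by Monte Carlo). Clustering is complete linkage on Euclidean distances
over the z-matrix with missing cells imputed to 0 (the control mean on
the z scale) — the linkage is the method's defining choice, the metric
and imputation are ours and are recorded in output metadata. PCA runs
on pre-processed, **un-normalized** betas (complete-case sites,
mean-centred SVD) to avoid circularity between normalization and
visual separation; group ellipses for groups of ≥ 3 samples use the
group mean and covariance with a Hotelling-T² (F-quantile) radius, the
small-sample multivariate-t construction.

The non-redundant DMP selection is a greedy correlation filter: while
any pair of signature rows has |Pearson r| above the cutoff (default
0.90, the conventional default of the procedure), remove the member of
the worst pair with the larger mean absolute correlation against the
surviving set (ties keep the lower genomic index). Constant rows
correlate 0 with everything.

`score_sample` is an extension beyond unsupervised classification: the
direction-aware mean z over signature sites (z × +1 for hyper sites,
×−1 for hypo), requiring ≥ 50% of signature sites observed. Held-out
controls score near 0; signature-matching samples score several SDs up.

## Confounder adjustment

Cell-type deconvolution solves, per sample, min ‖Rw − y‖² over the
marker CpGs subject to w ≥ 0, Σw ≤ 1 (SLSQP), with missing markers
dropped pairwise; the estimated proportions enter the site model as
covariates (one column dropped against the sum constraint). The
reference table is an input — the synthetic module ships a six-type
leukocyte-style reference — so no external data are baked in.

Batch screening tests the top principal components of the complete-case
beta matrix against age (Pearson), sex and batch (one-way F), flagging
p < 0.05. Surrogate variables come from residual PCA: residualize betas
on the primary design, take eigenvalue *fractions* of the residual
spectrum, and keep leading components whose fraction exceeds the 95th
percentile of 20 row-permuted, re-residualized null spectra (a
parallel-analysis calibration; permuted matrices must be re-projected
onto the residual space and compared on variance fractions, otherwise
the null is systematically biased). Components are taken contiguously
from the top, capped at 5. This deterministic, seedable variant stands
in for the iteratively reweighted SVA algorithm, whose settings the
discovery pipelines in this field rarely pin down.

## Null calibration

For k in 1..15 and `reps` draws per k (default 20), k controls are
drawn without replacement as pseudo-cases and the full site scan +
significance rule runs against the remaining controls; draws are
independent across reps. k = 1 forces the linear-model path by
arithmetic. Reported per-(k, rep) counts allow any summary to be
recomputed; the headline is mean / min / max of the count distribution.

## Synthetic cohorts

The generator emulates the statistical shape of a targeted
methyl-capture study: ~50k CpGs by default (a deliberate desk-scale
stand-in for the ~2M-CpG assays; all rates and thresholds are
per-site, so behavior transfers), 64 controls, case groups of 2–6,
autosomes plus a chrX compartment that QC removes. Islands hold ~55% of
CpGs at low baseline methylation (β ≈ 0.12), open sea high (β ≈ 0.85) —
the canonical bimodal landscape. Latent sample methylomes are Dirichlet
mixtures of cell-type profiles (divergent at 300 marker CpGs), plus
small age/sex/batch effects, plus the planted case effect, plus
Gaussian beta-scale noise (sd 0.05), clipped to [0, 1]. Planted regions
(islands and open-sea runs) have their baseline set to 0.5 in **all**
samples before the ±Δβ case shift, modelling disease-responsive regions
as intermediately methylated — this is what lets hypo effects of 0.2–0.4
exist at island sites without clipping. Observed data are counts:
coverage ~ NegBin(mean 100, size 10) via gamma-Poisson, methylated reads
~ Binomial(coverage, β), so the 10X filter, the outlier rule and the
missingness rule all bite realistically.

What the generator does **not** emulate: real genome coordinates or
island catalogs, sequence context, spatially correlated noise beyond
the planted blocks, bisulfite-conversion failure, or the heavy-tailed
coverage of real capture assays. Passing the recovery tests therefore
demonstrates the pipeline's statistical correctness under the stated
noise model, not clinical performance on patient methylomes.

## Numerical and degenerate-input conventions

- p-values are floored at the smallest positive double; p = 0 inputs to
  combination are clamped with a warning.
- Zero-variance Welch comparisons: equal means → p = 1; unequal → p at
  the floor, flagged.
- Constant or collinear design columns are pruned with warnings; losing
  the group column is an error.
- BH q-values propagate NaN for untestable sites.
- All randomness flows from explicit seeds; reruns are byte-identical,
  and every pipeline output embeds the config hash and seed.

## Problem sizes used in the checks

The test suite and acceptance script run the discovery scenario at 50k
CpGs (64 controls vs 4 cases, Δβ = 0.30), the null calibration at 20k
CpGs with 5 reps per k (reps is a free parameter of the calibration;
the default for production runs is 20), the GOM/LOM null at 360k
site-sample cells, and deconvolution recovery at 200 markers × 12
samples. These sizes were chosen as the smallest at which the targeted
rates (FDR, tail probabilities, recovery fractions) are measurable with
comfortable Monte-Carlo margins.
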