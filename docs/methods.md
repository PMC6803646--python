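# Methods

## Problem setting

Fixed-content qPCR arrays report, per probe and sample, the PCR cycle at
which fluorescence crosses threshold (Ct). Lower Ct means more template;
the instrument ceiling (cycle 40) means "undetected". On small clinical
cohorts — here, two groups of roughly 20 and 14 samples over ~754 miRNA
probes — most probes are censored in most samples, per-probe variance
estimates are noisy, and any classifier evaluation must confront severe
small-sample optimism. The pipeline addresses these three problems with,
respectively, explicit QC filters, empirical-Bayes variance moderation, and
repeated-split evaluation plus exact binomial intervals.

## QC and normalization

* **Probe filter.** A probe at Ct = 40 in *every* sample carries no
  information and is removed. The filter is idempotent and conserves
  counts (`n_in = n_removed + n_kept` is asserted in the QC report type).
* **Sample filter.** A sample in which *strictly more than* 80% of the
  remaining probes are undetected is removed. Because the reader clamps
  every value at the ceiling, "above 40" is implemented as Ct ≥ 40. The
  filter errors out if a whole group would vanish, since the downstream
  contrast needs both groups.
* **Reference probes.** Candidates must be undetected in at most 3 retained
  samples (an absolute count, as appropriate for ~34-sample cohorts; a
  fraction mode is available for other cohort sizes). Among eligible
  probes the k = 4 with the smallest interquartile range of Ct are chosen.
  IQR is Q3 − Q1 with the linear-interpolation quantile convention, ties
  break by probe ID ascending, and the ranking is computed *after* sample
  filtering, since normalization targets the retained cohort. The IQR is
  computed on all retained samples including 40s, so occasional censoring
  penalizes instability rather than hiding it.
* **Delta-Ct.** dCt(p, s) = Ct(p, s) − mean_ref Ct(ref, s). This removes
  per-sample loading/efficiency offsets exactly: adding any per-sample
  constant to all Cts leaves dCt unchanged (tested). Undetected values
  that survive QC stay as numeric 40 through normalization and statistics;
  treating them as missing would unbalance the per-probe designs on a
  cohort this small.

## Differential expression

The expression proxy is e = −dCt, so positive logFC = higher abundance in
cancer; Ct is log2-scale, so logFC is in doublings. Per probe, logFC is the
difference of group means and s² the pooled within-group variance on
d = n₁ + n₂ − 2 df. The variance prior (d₀, s₀²) is estimated by matching
moments of z = log s²: with e_g = z_g − ψ(d/2) + log(d/2),

    ψ′(d₀/2) = var(e_g) − ψ′(d/2),      s₀² = exp( mean(e_g) + ψ(d₀/2) − log(d₀/2) ),

where the inverse trigamma is obtained by Brent root-finding on
[1e-8, 1e9] (tolerance 1e-12); when the variance excess is non-positive the
prior df is infinite and every probe shrinks fully to s₀² = exp(mean e_g).
Estimated d₀ above 1e7 is declared infinite. Probes with s² = 0 are
excluded from moment matching (their log-variance is −∞) but still receive
the moderated variance d₀s₀²/(d₀ + d). The moderated t is referred to
Student t on d₀ + d df (normal when d₀ = ∞), two-sided. A test fixture
cross-checks logFC, d₀, s₀², t and p against the reference Bioconductor
implementation of this moderation (limma, run through Rscript) to ≤1e-4
relative error.

BH step-up adjustment is implemented directly (sort, cumulative minimum of
m·p₍ⱼ₎/j from the top, cap at 1) and verified against an O(m²) direct
minimization and against statsmodels. The candidate gate is strict on both
sides: adj p < 0.05 **and** |logFC| > 3.

Choices left open by common practice, decided here: plain moderation (no
variance trend, no robust down-weighting); two-group contrast only, no
covariates; two-sided p-values. The total-df cap some implementations apply
when d₀ is huge is not replicated — on panels this size it never binds for
finite d₀ fits.

The logFC sign convention means a probe printed with negative logFC is
*lower* in cancer. Prose that paraphrases a logFC of −13.8 as "13-fold" is
internally inconsistent with log2 units and is not reproduced; values are
reported in delta-Ct (log2-like) units throughout.

## Single-marker evaluation

Each candidate's expression proxy is the lone feature of a logistic
regression fit by Newton/IRLS (convergence when the largest coefficient
update < 1e-8, max 50 iterations). Perfect or quasi-separation — common
with strong markers on 34 samples — is detected when |β₁|·sd(x) exceeds 15
or any working probability is within 1e-10 of 0/1; the last stable
coefficients are returned flagged `separated`, which leaves score
*orderings*, hence AUC and thresholded predictions, intact. The
classification cutoff is probability 0.5 (ties predict cancer);
configurable.

* **Repeated splits.** 500 stratified 2:1 splits; per class, round(2n/3)
  samples train (13 of 20 controls, 9 of 14 cancers) and the rest
  validate. Stratification is required: unstratified splits of a 14-sample
  class can produce single-class training sets. Each metric (Mann–Whitney
  AUC with half-tie correction, accuracy, sensitivity, specificity) is
  summarized by its mean over repeats and the normal-theory 95% CI of the
  mean (±1.96·sd/√R) — per-split percentile intervals are far wider and are
  available behind a flag-level choice in the API.
* **Whole cohort.** Resubstitution metrics from a fit on all samples, with
  an exact Clopper–Pearson interval on accuracy: lower =
  Beta⁻¹(α/2; x, n−x+1), upper = Beta⁻¹(1−α/2; x+1, n−x), endpoints 0/1 at
  x = 0/n. Resubstitution is reported as such; on 34 samples it is
  optimistic, which is precisely why the exact interval and the
  repeated-split summary accompany it.
* **Ranking.** Whole-cohort accuracy descending, ties by AUC then probe ID.

## Synthetic cohorts

The generator emulates the data regime the pipeline assumes: per-probe
baseline Ct uniform on [18, 34]; Gaussian per-well noise (sd 0.8 Ct, or
0.15 for the 6 designed reference probes); 30% of probes forced above the
ceiling (all-40); 5 + 9 spiked probes shifting the cancer group mean by ±5
Ct by default (spike-recovery tests use ±6); values censored to exactly 40.
Defaults produce 754 probes × (20 + 14) samples. A single seed drives
per-purpose independent streams, with one noise stream per probe, so
enlarging the panel appends probes without reshuffling existing values.

What it does **not** emulate: amplification chemistry and preamplification
bias, inter-plate batch effects, heteroscedasticity between probes beyond
the reference/non-reference split, correlated miRNAs, and partial censoring
of the *informative* tail (real "detected in 288 of 754" patterns arise
from a continuum of expression near the ceiling, not a binary
detected/undetected dichotomy). Consequently, passing tests demonstrate
that the pipeline's statistics behave correctly under their stated
assumptions — not that those assumptions hold for any particular real
cohort. With the default effect size (5 Ct ≈ 32-fold at noise 0.8) spiked
markers separate the groups almost perfectly, so synthetic whole-cohort
accuracies saturate near 1.0; real cohorts, with weaker effects and
biological overlap, sit lower.

## Numerical and degenerate-input choices

* Undetected sentinels on read: `Undetermined`, `NA`, empty, any value
  > 40 (clamped, logged). Values ≤ 0 are rejected with coordinates.
* Constant features and single-class labels are errors in the classifier;
  an empty candidate list is a *valid* pipeline outcome (empty report,
  exit success).
* All-zero variance vectors abort moderation ("degenerate variance
  distribution"); zero moderated variance yields p = 0 with a warning.
* Determinism: one master seed fixes generation, splits, and therefore
  every output table bit-for-bit; the run manifest records config, input
  digests and stage counts.

## Test-suite problem sizes

Monte-Carlo checks run at sizes chosen to keep the default suite quick
while leaving no statistical ambiguity: type-I calibration at 20 seeds ×
500 probes, generator null calibration at 200 seeds × small panels, prior
recovery at 5000 probes, FDR control at 20 full-pipeline null cohorts, and
split-engine calibration at 200–500 repeats.
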