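# Methods

## Scope and data model

All analyses operate on a sample × feature TPM matrix (`ExpressionMatrix`),
a clinical table (`sample_id, time, event, …`), a cell line × drug
IC50/EC50 table, a long-format gene-effect table with control labels, and a
triplicate qPCR plate. Expression enters every statistical procedure as
log2(TPM + 1); raw TPM is used only for the absolute cutoff rule, which is
defined on the TPM scale.

## EMT quadrant classifier

Aggregate scores are per-sample means of marker log2(TPM+1): mesenchymal
over {ZEB1, VIM, FN1}, epithelial over the 11-gene epithelial set. A sample
is "top" on an axis iff its aggregate score is **strictly greater** than
the cohort median of that score; the two binary flags map to the four
phenotypes (top/top → HighOverlap, top/bottom → Mesenchymal, bottom/top →
Epithelial, bottom/bottom → LowOverlap). Consequences of the tie rule: a
cohort of identical samples is all LowOverlap, and a sample exactly at the
median is never "top". The same rule drives `split_by_median_gene`.

Two scoring conventions exist in the literature for "rank-based" aggregate
signatures; the default (`score_mode="mean_log"`) ranks the per-sample
mean of marker values, the alternative (`"mean_rank"`) averages each
marker's within-cohort rank. Both are rank-based at the decision stage, so
the classification is invariant to any strictly increasing transform of
the aggregate scores. The log2 transform before averaging prevents a
single high-abundance marker from dominating the mean.

## Survival stratification

`stratify_by_cutoff` labels a sample high iff value ≥ cutoff (default TPM
1.5); the boundary belongs to the high group. Kaplan–Meier curves,
k-group unweighted log-rank tests, and the univariate Cox
proportional-hazards estimate are delegated to lifelines (Breslow tie
handling; Newton iterations tightened to precision 1e-10 so small worked
examples agree with closed-form partial-likelihood maximisers to ~1e-9).
The HR confidence interval is the Wald interval on the log scale,
exponentiated. Strata where a group is empty, no events occur, or all
events fall on one side are reported as non-estimable rather than dropped
or raised, so `per_phenotype_survival` always returns exactly four rows.

The event column is treated generically (overall vs disease-specific
survival is the caller's semantic choice). No multivariate adjustment and
no competing risks — deliberately out of scope.

## Drug response and differential expression

Categorization uses the sample SD (n−1) and strict inequalities: values
exactly at mean ± 0.5·SD are partial. The rule is affine-invariant, so it
is insensitive to whether IC50s arrive on the log scale. Differential
expression between resistant and sensitive lines (partial excluded) is a
two-sided pooled-variance t-test per feature on log2(TPM+1); Welch is
available via a flag, and Benjamini–Hochberg adjustment is provided as an
opt-in helper (per-gene uncorrected p-values are the default reporting
convention here).

## Dependency scores

Only the output convention of large knockout/knockdown screens is
implemented: the per-cell-line two-point affine anchoring
f(x) = (x − m_ne)/(m_ne − m_e), which pins the non-essential control
median at exactly 0 and the essential control median at exactly −1
(exact because an affine map commutes with the median, including the
even-n midpoint). The screen models that *produce* raw gene effects are
not reimplemented. A dependency call requires normalized score ≤ −0.5;
the boundary value counts as dependent.

## qPCR quantification

Replicate Ct values are averaged; ΔCt = Ct_target − Ct_housekeeping;
ΔΔCt subtracts the reference sample's ΔCt; fold change = 2^−ΔΔCt. The
reference sample's fold change is exactly 1. Technical-replicate
variance modelling (mixed effects) is out of scope.

## Statistical kernel

Thin wrappers over scipy: Student's/Welch t, Pearson correlation, one-way
ANOVA, Tukey HSD (studentized range), Pearson chi-square without
continuity correction (expected counts reported, with a flag when any
expected cell < 5). Partial correlation uses the first-order recursion
r_xy·z = (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)) with a t test on n−3
df; tests verify it against the residual-regression definition. Two
constant equal samples yield t = 0, p = 1 rather than an error. All
p-values are reported in (0, 1].

## Synthetic-data generators

The generators define the study conditions the tests and the acceptance
script run under; they are deterministic functions of `SimConfig`
(identical seed → byte-identical outputs).

**Isoform expression.** log2(TPM+1) of the KRAB isoform is Gaussian with
scale `logsd` (default 0.35) and location placed so that
P(TPM ≥ 1.5) = `high_fraction` (default 0.17, the emulated cohort's
high-expression prevalence). Each sample's side of the cutoff is planted
explicitly — a Bernoulli(0.17) label followed by a truncated normal on
that side — so the mixture marginal is exactly the untruncated normal
while the planted label coincides exactly with the TPM ≥ 1.5 rule. The
KRAB-less isoform is conditionally Gaussian given KRAB with correlation
`iso_corr_rho` (default 0.6) and location 0.35 log2 units lower (the KRAB
isoform dominates; the gap and scale keep the TPM = 0 floor below ~1% so
log-scale analyses see essentially exactly Gaussian values, and the
planted correlation is recovered by Pearson's r). `ZNF71_overall` is the
sum of the two isoform TPMs.

**EMT markers.** Two latent axes (epithelial, mesenchymal) are standard
bivariate normal with correlation `emt_axis_corr` (default −0.3:
moderately antagonistic programs that still allow hybrid states). Each
marker's log2 expression is baseline + loading·axis + N(0, noise_sd)
(defaults 3.0, 1.5, 0.5); TPM = 2^x − 1 floored at 0. The planted
phenotype is the median-split quadrant of the latent axes themselves. A
stromal score (ESTIMATE-like scale, ×800) is drawn correlated with the
mesenchymal axis (default r = 0.7); stromal deconvolution itself is not
modelled.

**Survival.** Event times are exponential with hazard
`baseline_hazard`·exp(`true_log_hr`·exposed), exposure being the planted
high-KRAB label (optionally restricted to one latent phenotype via
`hr_phenotype`, used to plant phenotype-specific effects). Censoring is
administrative, uniform on (0, `censor_max`). Defaults (0.037 events per
month, 60 months) give ~60–65% observed events. `true_log_hr` defaults to
log 1.686, the planted prognostic effect of the high-expression group.
Event rates are generator defaults, not estimates of any real cohort.

**Drug response.** Per drug, log-IC50 and log-EC50 are Gaussian; hidden
resistant/partial/sensitive labels are derived from the generating
distribution's own mean ± 0.5·SD, and resistant lines receive a planted
log2 expression shift (default +1 in `ZNF71_overall` and `ZNF71_KRAB` for
docetaxel and paclitaxel, 0 elsewhere). With shift 0 the panel is an
exact null for the differential-expression test. `n_background_genes`
adds independent null genes for calibration experiments. Because features
are shifted independently on the log scale, the overall = KRAB + KRAB-less
identity is not preserved after a planted shift; the matrix is a
statistical emulation, not a constrained quantification.

**Dependency and qPCR.** Gene effects are Gaussian per control class
(essential N(−1.2, 0.2), non-essential N(0.05, 0.15), query N(0, 0.15) —
a query gene that does not affect growth). qPCR plates plant per-sample
true ΔCt values (drawn or given explicitly via `delta_cts`) and add
Gaussian technical noise to each replicate; the first sample is the
reference.

**What the generators do not emulate:** count noise and library-size
effects, isoform-level quantification uncertainty, non-proportional
hazards, informative censoring, batch effects, drug–drug correlation
structure, and real marker co-expression beyond the two-axis model.
Passing recovery tests therefore demonstrates correctness of the
*procedures* under their stated assumptions, not performance on real
cohorts.

## Verification scale and thresholds

The test suite's heavier checks use these problem sizes, chosen as
routine desk-scale experiments:

- hazard-ratio recovery: 500 cohorts of 197 tumors; the mean of the HR
  estimates must fall within 5% of the planted 1.686 and the Wald 95% CI
  must cover truth in 92–97% of cohorts. The mean of exp(β̂) carries a
  small positive Jensen bias (~+2.5% at this event count), which the 5%
  band accommodates.
- classifier oracle equivalence: 1000 random 20-sample matrices against a
  brute-force median-split oracle, exact agreement.
- null calibration at α = 0.05: 10,000 replicates for t, ANOVA and
  chi-square (vector-cheap), 4,000 for the log-rank (costlier per call);
  the acceptance band is [0.04, 0.06]. Chi-square null tables use n=1000
  because Pearson's statistic on discrete 2×2 tables approaches its
  nominal level slowly.
- phenotype recovery: "well-separated axes" means marker loading 4.0,
  residual SD 0.1, baseline 8.0; ≥95% of samples must recover their
  planted quadrant. The phenotype-restricted survival effect is planted
  at log HR = log 6 (sized for ≥0.8 log-rank power in a ~49-sample
  stratum with an ~8-vs-41 split); the other strata must stay near the
  nominal level, bounded at 0.12 because the asymptotic log-rank is
  mildly anticonservative (~0.06–0.075) at that stratum size and split —
  a property of the test, not of the implementation.
- exact identities (KM = empirical survival without censoring; control
  medians 0/−1; reference fold change 1) are asserted at 1e-12.

## Known limitations

- The Cox fit is univariate by design; confounding by stage or histology
  is not adjusted for.
- The quadrant classifier's median-split thresholds are cohort-relative:
  calls are not transferable across cohorts without re-ranking.
- Categorization thresholds (mean ± 0.5·SD) are panel-relative in the
  same way and sensitive to panel composition.
- The asymptotic chi-square and log-rank p-values are approximations at
  small strata; the package reports a low-expected-count flag for the
  former but does not switch to exact tests.
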