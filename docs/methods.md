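# Methods

This note documents the models, defaults and numerical choices behind
`depmark`, and what the synthetic studies do and do not show about real data.

## Study design being modelled

The mouse arm is a 2x2 stress-by-fluoxetine design (NS-C, S-C, S-FLX, NS-FLX;
8 mice per group) profiled in whole blood, dentate gyrus and anterior
cingulate cortex on a log2 microarray intensity scale. Stressed treated mice
are split post hoc into responders and nonresponders by the sum of two
coat-state scores (cutoff 2, inclusive on the responder side). The human arm
is a longitudinal case/control cohort: 10 patients in a severe major
depressive episode (HDRS >= 20 at inclusion, antidepressant-free at baseline)
and 10 matched controls, assayed by duplicate RT-qPCR at weeks 0, 2, 8, 30.

## Synthetic mouse generator

Probe baselines are Gaussian on the log2 scale (mean 8 in blood, sd 1.5),
which makes linear intensities log-normal — a standard stand-in for
quantile-normalized single-channel array data; the true intensity
distribution of any given platform is not modelled. Brain baselines are
shifted by log2(brain_intensity_factor) so the expected linear-scale mean
ratio equals the factor (default 2.5, kept inside the observed 2-3x band).
Residual noise is additive Gaussian on log2 values, sd 0.5 by default,
against a planted effect of 1.0 log2 units.

Planted classes (defaults: 60 stress-only, 40 stress-reversal, 30
fluoxetine-only, 40 concordant split evenly up/down, 30 discordant, out of
2000 probes per tissue, scalable to the ~17k/33k probes of the real arrays):

| class | shifted samples | tissues |
|---|---|---|
| stress_only | all stressed (S-C, S-FLX-R, S-FLX-NR) | blood |
| stress_reversal | S-C and S-FLX-NR only | blood |
| flx_only | all fluoxetine-treated | blood |
| concordant_up/down | S-C and S-FLX-NR (fixed sign) | blood + DG + ACC |
| discordant | S-C and S-FLX-NR, sign flipped in brain | blood vs DG/ACC |

Responder status is Bernoulli(5/8) per S-FLX mouse; coat scores are then
drawn on the correct side of the cutoff, so phenotype classification is
exactly recoverable and the "restored in responders" pattern is well defined.
Behavioral measures (weight gain raised by stress, nest building suppressed,
both restored in responders) are drawn with overlapping Gaussians so group
tests are significant but not degenerate. An off-by-default `outlier_mouse`
option adds a +2 log2 global shift to one S-C sample to exercise
outlier-exclusion logic.

What passing tests show: the pipeline's operations recover planted structure
at realistic effect/noise ratios. What they do not show: robustness to probe
cross-hybridisation, batch effects, correlated gene modules, or non-Gaussian
heavy-tailed noise — none of which the generator emulates.

## Synthetic human generator

Expression is generated directly on the relative-quantity (RQ) scale the
validation statistics consume (RQ 1 = control-like), then converted to cycle
thresholds by Ct = base_g − log2(e) + N(0, ct_noise_sd) per replicate
(defaults: gene baselines 22-30 cycles, noise 0.15 cycles, two replicates,
references CRYL1 at 24 and SV2A at 32 cycles, all clipped to [10, 40]).

* Trait genes: patients carry a constant additive offset
  2^trait_offset_log2 − 1 (default offset 1.0 log2, i.e. ~2-fold).
* State genes: a patient's RQ change from baseline equals
  state_slope x (concurrent HDRS change), slope −0.1 RQ per HDRS point by
  default — magnitudes consistent with reported regressions of roughly ten
  HDRS points per unit RQ change.
* Prediction genes: the baseline-to-week-2 RQ change equals
  prediction_slope x (baseline-to-week-8 HDRS change).

Positive slopes combined with the large HDRS declines of improving patients
would push RQ negative; quantities are floored at 0.05, so couplings are
exact only while RQ stays positive (negative slopes at the default
magnitudes always do).

Subject-level scatter (sd 0.15) is additive on the RQ scale for patients, so
it cancels exactly in visit differences, and is centred per gene in log2
space for controls, so the control calibrator's geometric-mean RQ is exactly
1 and zero-noise runs invert the planted expression exactly. HDRS
trajectories start at baseline_min + U(0, 8) and decay by visit-specific
fractions (means 0.75, 0.45, 0.30 at weeks 2, 8, 30; sds 0.10, 0.20, 0.15,
clipped to [0.05, 0.95]) — the deliberate heterogeneity at week 8 gives the
change-score regressions realistic predictor spread (sd(ΔHDRS) ~ 4).

## Statistical components

**Contrasts.** Pooled-variance (Student) two-sample t per gene; p-values are
floored at the smallest positive double so −log10(p) stays finite; sign is +1
when the first group's mean is at least the second's.

**Reversal filter.** Keep iff stress p < 0.05, recovery p < 0.05, recovery
sign opposite to stress sign, and drug-alone p >= 0.05. No multiplicity
control is applied (recorded in the table metadata); under an independent
null the analytic keep rate is 0.05 x 0.05 x 0.5 x 0.95 ≈ 1.19e-3, which the
acceptance suite verifies by simulation. The stress-specific filter treats
fold change symmetrically, max(FC, 1/FC) > 1.2, so down-regulation qualifies.

**SAM.** Classical two-class unpaired d-statistic. s0 is chosen from the
5%-quantiles of the per-gene standard errors to minimise the coefficient of
variation of the window-wise MAD of d. Cut points per Δ come from the first
crossing of the sorted observed d against the permutation-mean order
statistics, scanning from the centre outward; FDR(Δ) is the median
permutation false-call count over observed calls (no pi0 shrinkage —
conservative). Permutations are uniform label reassignments, exhaustive when
the number of distinct assignments is at most n_perm (default 200); strict
"balanced" permutation is undefined for the odd group sizes that arise after
outlier removal, so plain permutations are used throughout.

**RRHO.** The map spans both full lists with step max(1, N/100) (~100x100
grids). Cells at or above the expectation i·j/N are scored with the exact
upper hypergeometric tail, the rest with the lower tail (mode `two_ends`;
an `over_only` variant scores every cell with the upper tail). Tails are
summed in log space via log-gamma, capped at −log10(p) = 320. Per-cell
p-values are strongly dependent across the map, so the summary statistic is
the map maximum, optionally reported with its percentile in an
independent-permutation null; no per-cell multiplicity correction is
attempted. A fully anti-correlated pair attains the minimum possible overlap
in every top-top cell, so reversal appears as under-enrichment on the map;
head-versus-tail over-enrichment is measured by the quadrant extraction,
which rescans with the relevant list read from its tail and returns the
intersection of the argmax segment pair. Extraction quadrant boundaries are
the sign changes of the two score vectors. Ties in ranking are broken by
gene id; ties in the argmax go to the lexicographically smallest cell.

**Mixed ANOVA.** Two-way mixed design, one between factor (group) and one
within factor (visit), complete cases only (dropped subjects reported).
Sums of squares use the group-size-weighted decomposition, which is exactly
additive (verified to 1e-9 against a brute-force oracle and cross-checked
against an independent implementation). Group F uses subjects-within-group
error; visit and interaction use the visit x subjects error. Partial
η² = SS_effect / (SS_effect + SS_own_error). No sphericity correction by
default (the assumption is reported); a Greenhouse-Geisser flag exists and
is recorded in output metadata when used. All-constant input reports F = 0,
p = 1 rather than 0/0.

**Change-score regressions.** OLS of ΔHDRS on ΔRQ with t-based two-sided p
and CI b ± t_{0.975, n−2}·SE; the CI excludes zero exactly when p < 0.05.
ΔRQ is a difference of relative quantities by default; a log2-RQ option
exists and is recorded in metadata (which scale the original analyses used
is not stated, so neither is asserted). A gene with zero expression change
has no defined slope and is reported NaN/ns rather than aborting the table.
Calls are three-level: significant (< 0.05), trend (< 0.1), ns. A trait call
additionally requires visit and interaction effects to be non-significant.

**qPCR.** Duplicate spread above 0.5 cycles and single replicates are
flagged, never dropped; the low-expression gate (Ct ≤ 35 in ≥ 80% of
samples, boundary inclusive) is the only exclusion, and excluded genes still
appear in the verdict table as `excluded_low_expression`. These QC numbers
are conventional defaults, configurable, not claims about the original
assays. Reference strata: mean Ct ≤ 30 uses the first reference gene. The
mouse calibrator is the NS-C group mean; the human calibrator is the control
group across all four visits.

## Problem sizes and determinism

Default simulations use 2000 probes per tissue, 8 mice per group, and
13-gene human panels — sizes chosen so the full test suite and the
acceptance script each complete in a few minutes while keeping every
power/calibration property measurable. All randomness descends from a single
integer seed through named substreams; identical configs and seeds reproduce
byte-identical artifacts, and the file-based runs write a JSON manifest
(inputs, thresholds, seeds, group sizes) sufficient to re-execute any stage.

## Known limitations

* The probe-filtering rule that produces a real platform's "analyzable
  probe" counts is upstream of this pipeline; matrices are accepted as
  given (plus an optional low-intensity floor, off by default).
* Hand-picking of a final validation panel from eligible candidates involves
  judgment the ranking cannot reproduce; the candidate table ranks by
  evidence-flag count and blood stress p only.
* Ontology enrichment is a generic hypergeometric over-representation test
  with Bonferroni correction over GMT sets — a stand-in for curated
  annotation services, with the background defaulting to the tissue's
  contrast universe.
* No moderated-variance differential expression, no mixed-effects
  longitudinal models, and no heatmap rendering (orderings and matrices are
  exported for any plotting tool).
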