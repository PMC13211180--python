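# Methods

`ibrtox` implements a multi-biomarker analysis workflow for sub-chronic
aquatic exposure studies: a panel of oxidative-stress biomarkers (superoxide
dismutase SOD, glutathione peroxidase GPx, glutathione S-transferase GST,
malondialdehyde MDA) measured in three tissues of a decapod crustacean, plus
hemocyte/hepatocyte viability, across a control and three exposure
concentrations (0.5, 5, 25 mg/L of a water-soluble polymer) sampled at 10 and
20 days. This note records the models, the defaults and why, and what the
synthetic generator does and does not emulate.

## Threshold-based integrative biomarker response (IBR-T)

For each tissue x day stratum, the control group defines per biomarker a
reference R (control median) and a threshold T (control 95th percentile),
both by linear interpolation on order statistics (position h = (n-1)p + 1).
Per treatment t the log-ratio L_t = ln(mean_t / R) is standardised by the
sample SD (n-1 denominator) of {L_t} taken across all treatments including
the control: z_t = L_t / sd(L). A biomarker is included for treatment t when
mean_t strictly exceeds T; the IBR-T score is the mean of |z| over included
biomarkers, and 0 when none is included, so every group (control included)
carries a defined score.

Choices that were genuinely open, and how they were resolved:

- **Log base.** Natural log. Any base cancels in z after the SD division, so
  the choice is observationally neutral; it is recorded in the results
  metadata rather than left implicit.
- **SD "across treatments".** Taken over the treatment *log-ratios* within
  one (tissue, day, biomarker), not over raw means — the only reading under
  which per-day, per-tissue scores are computable from group means alone.
  The choice is emitted in `IBRTResults.settings`.
- **Induction only.** Inclusion requires strict upward exceedance of the
  control 95th percentile; suppression below the control's lower tail never
  counts. A symmetric option (`symmetric_threshold=True`, mirrored lower
  threshold R^2/T) exists but is off by default.
- **Stratification.** References and thresholds come from the same day's
  control group, because scores are reported per tissue and day;
  `pool_days=True` pools controls across days instead.
- **Degenerate cases.** sd(L) = 0 maps all z to 0; no included biomarkers
  maps the score to 0 (not NaN) so treatment profiles remain comparable.

Useful consequences, all under test: the score is invariant to rescaling any
biomarker's unit; a control group scores 0 unless its own mean exceeds its
own 95th percentile (rare at these n); with noise-free dose-monotone effects
the top dose never scores below a lower dose.

## Nonparametric group testing

Kruskal–Wallis with midranks and the standard tie correction; p-values from
the chi-square approximation with k-1 degrees of freedom, the standard
choice at group sizes around 7 (guideline minimum about 5 per group). An
exhaustive-permutation p (`method="exact"`) is available for pooled samples
up to N = 12 and is used in tests to validate the null distribution. When
every pooled value is identical the statistic is 0 and p = 1 by convention.

Dunn's z for a pair (i, j) uses the pooled-variance form with tie
correction. The default applies **no** multiplicity adjustment — the most
literal reading of a bare "Dunn's post hoc test" — with Holm and Bonferroni
switchable; the chosen adjustment is recorded in the output. Stars follow
the strict bands * p<0.05, ** p<0.01, *** p<0.001.

## Ordination

Variables are z-scored (sample SD over observed entries; constant columns
become zeros with a warning). Missing cells — structural here, since no
compartment carries every variable — are filled by iterative low-rank
(EM-PCA) imputation: initialise at column means, alternate a
rank-`n_components` SVD reconstruction of the column-centred matrix with
reimposition of observed cells, stop when imputed cells move less than `tol`
(default 1e-6) or after `max_iter` (500). Defaults `n_components=2`: the
imputation rank used by the original analysis is unreported, and 2 matches
the embedding dimension; the setting is recorded in results metadata. The
scheme recovers a masked cell of an exactly rank-1 matrix to 1e-8 and, under
10% missing-completely-at-random masking of rank-2-plus-noise data,
estimates the underlying signal with RMSE below the noise SD (both under
test).

Non-metric MDS minimises Kruskal stress-1,
sqrt(sum (dhat - d)^2 / sum d^2), over k = 2 configurations of the Euclidean
distance matrix. Disparities dhat are the isotonic (pool-adjacent-violators)
regression of configuration distances on dissimilarity ranks with *primary*
tie treatment (tied dissimilarities ordered by current distance, hence
unconstrained among themselves); configurations update by Guttman-transform
majorization. One deterministic classical-scaling (PCoA) start plus 99
seeded random starts (substream per start index, so enlarging the start set
never raises the returned stress); inner convergence at stress change
< 1e-7 or 300 iterations. The classical start itself is kept as a candidate,
so the returned stress never exceeds the classical start's. The returned
configuration is centred, rotated to principal axes, and sign-fixed for
determinism. Stress below 0.2 is classified acceptable, the conventional
cutoff.

## Factorial model, Type III ANOVA

Responses (enzyme activities, MDA, and viability as one additional biomarker
level) are z-scored per biomarker type to remove scale differences, then
modelled as fixed effects of Treatment (4), Day (2), Matrix (4 compartments
including hemolymph) and Biomarker (5 levels including viability), with the
Treatment:Day, Treatment:Biomarker and Treatment:Day:Biomarker interactions;
a full-factorial term set is available but off by default. Viability enters
through the Neutral Red assay only, so Biomarker contributes 4 degrees of
freedom; Trypan Blue results are analysed alongside in the rank tests.

Factors are coded with sum-to-zero (deviation) contrasts; Type III sums of
squares are computed by the RSS-difference definition (drop the term's
columns, keep everything else). Treatment/dummy coding is refused with an
explanatory error because Type III hypotheses are contrast-dependent. On
balanced designs the Type III and sequential decompositions coincide (under
test, as is agreement with an independent general-linear-model route on
unbalanced data).

## Synthetic study generator

The generator draws biomarker values as
`baseline * exp(dose_slope * g(day) * log1p(dose) + eps)` with
`eps ~ N(0, sigma)`, `sigma = sqrt(ln(1 + cv^2))`, `g(10) = 1`,
`g(20) = day_gain` — positive, right-skewed, with multiplicative dose- and
time-dependent effects and exact null at dose 0. Defaults: cv 0.25 (typical
between-animal variation for tissue enzyme activities), dose_slope 0.21
(roughly a doubling of a responsive biomarker at the top dose after 10
days), day_gain 1.5 (intensification with exposure time), n_per_cell 7 (a
15-animal treatment group split conservatively over two sampling days, the
split being unreported), and baselines of realistic magnitude per tissue and
biomarker in the declared units. Every (tissue, treatment, day, biomarker)
cell has its own seed-keyed substream, so adding cells never perturbs
existing draws and a seed fully determines the table.

`cv = 0` selects the exact noise-free mode used by the deterministic null
and monotonicity checks. This is a genuine mode rather than a limit: the
IBR-T is scale-invariant, so shrinking cv does not shrink the probability
that a treated mean crosses the control's 95th percentile — only cv = 0
collapses it.

Viability percentages are truncated-normal on [0, 100] per (compartment,
assay, treatment, day) cell, with hemolymph means above 99% throughout and
hepatopancreas means showing dose- and time-dependent declines (e.g. the
Neutral Red top-dose day-10 cell at 85.46 +/- 5.84 and the strongest decline
at the middle dose after 20 days, 69.90 +/- 9.30).

What the generator does **not** emulate: within-animal correlation between
biomarkers and tissues (each cell draws independently, so passing tests say
nothing about correlated panels), sex or size covariates, mortality or
molting, non-lognormal contamination, and any water-chemistry dynamics.
Tests passing on this generator demonstrate correctness of the statistical
machinery under the declared design, not robustness to those real-data
features.

## Problem sizes and numerics

The default pipeline analyses 672 biomarker rows plus 224 viability rows
(56 animals x 4 compartments in the ordination view; 784 observations, 745
residual df in the factorial model). Calibration checks use 10,000 null
simulations for the omnibus test and 5,000 for ANOVA p-uniformity;
permutation cross-checks enumerate all 1,680 assignments at N = 9. Key
tolerances: IBR-T oracle agreement 1e-12; rank-1 imputation recovery 1e-8;
balanced Type III vs sequential 1e-9 relative; NMDS perfect-embedding
stress 1e-3.

## Known limitations

- The IBR-T inclusion rule is a fixed-threshold exceedance, not a formal
  test; at small control n the 95th percentile is interpolated from few
  order statistics and is itself noisy.
- The chi-square omnibus p is approximate at n = 7 per group (slightly
  conservative in the calibration check); the exact method is exponential in
  N and only practical for tiny samples.
- EM-PCA imputation assumes an approximately low-rank structure; with
  heavily structured missingness (a whole compartment lacking most
  variables) imputed values lean on the between-variable correlation of the
  observed compartments.
- The factorial model treats animals as independent observations across
  tissues, as the response-set construction implies; no random animal effect
  is fitted.
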