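# Methods

This note records the statistical models, conventions and numerical
choices behind plaquekit, and what the synthetic cohorts do and do not
establish about real imaging data.

## Coordinates and the data model

Longitudinal positions are millimetres from the proximal end of the
segment of interest, increasing in the pullback direction; positions are
authoritative and may be irregular (end-diastolic gating does not produce
uniform spacing), so every volume is a trapezoidal integral over actual
positions rather than frame count x nominal spacing. The circumference is
discretised into 360 one-degree bins with a fixed reference angle;
circumferential registration between modalities is taken as given, which
is safe because every burden index depends only on bin counts, never on
absolute rotation. Tissue flags are multi-label: a bin can be both LIPID
(chemogram) and CA (calcium arc) because NIRS detects lipid irrespective
of overlying calcium; forcing exclusive classes would impose an unstated
precedence. LCBI and CaBI are therefore computed on independent masks,
and every grid cell counts in the denominator (no guide-wire exclusion —
chemogram no-signal handling is not modelled).

## Plaque metrics

`maxLCBI_4mm` windows are anchored at frame positions: for each start
column the window is the maximal run of columns spanning <= 4 mm. With
typical <= 1 mm spacing the discretisation error of not sliding the
window continuously is below the resolution of the index. Segments
shorter than 4 mm return the whole-segment LCBI with a warning rather
than an error, so batch runs keep going while the condition stays
auditable. The Hounsfield-unit classifier uses half-open intervals
[low, high) — a value exactly at a threshold joins the upper class — with
shipped defaults 76 / 131 / 351 HU chosen by the implementer from the
histology-validation literature for quantitative CTA; they are
configuration, not constants, because software calibrations differ.

## Lesion rule

A lesion needs >= 3 consecutive frames with PB >= 40%; two qualifying
runs are one lesion when the sub-threshold gap between them (last frame
position of the earlier run to first of the later) is strictly shorter
than 5 mm — a gap of exactly 5 mm separates. Merging chains transitively,
and 1–2-frame qualifying runs survive only by being absorbed into a chain
that contains a >= 3-frame run: the separation rule concerns gaps of
insignificant atheroma, not run sizes. References and the remodelling
index have no universal formula; the convention here is the
least-diseased (minimum-PB) frame within 5 mm on each side of the lesion
(excluding frames inside any lesion), reference areas averaging the
available sides (one-sided is flagged), and remodelling index = vessel
area at the MLA frame / reference vessel area. The anchor is exposed in
`LesionPolicy` as a declared policy. Lesions transfer to CTA
frame-for-frame through the pairing, and CTA lesion metrics are computed
on the transferred span regardless of CTA plaque burden — the definition
is anchored on the reference modality.

## Agreement statistics

*Wilcoxon*: zero differences dropped; exact distribution for n <= 25
without ties, else the normal approximation with continuity and tie
correction.

*Bland–Altman*: parametric limits are mean +/- 1.96 x sample SD (ddof 1).
The nonparametric variant (used at segment and lesion level, where
samples are small and skewed) takes the median and the 2.5th/97.5th
percentiles as intercept-only quantile regressions — i.e. pinball-loss
minimisers, the convention that keeps results platform-reproducible. The
same lower-quantile convention drives tercile/decile stratification, with
ties at a cut-point assigned to the lower group.

*ICC*: the agreement model is `y = mu + f(ca) + s_target + m_modality + e`
with random intercepts for the measurement target (segment, lesion or
matched frame pair) and for modality, fitted by REML;
`ICC(A,2) = var_s / (var_s + (var_m + var_e)/2)` (absolute agreement,
average of the two modalities), clipped to [-1, 1] with variances floored
at zero. Three fitting routes give the same estimand:

- balanced, unadjusted data: the closed-form ANOVA variance components,
  which coincide with REML on balanced crossed designs (this is also what
  makes a 2,000-resample bootstrap affordable);
- covariate-adjusted or unbalanced data: `statsmodels` MixedLM with the
  two crossed effects as variance components, the outcome standardised
  internally (the ICC is scale-invariant and raw volumes of ~10^2 mm^3
  otherwise stall the optimiser); a REML fit that stalls on the variance
  boundary falls back, with a warning, to the closed form when the data
  are balanced;
- covariate-adjusted data with very many targets (frame level, where a
  random intercept per matched pair is beyond a dense mixed-model
  design): the restricted-cubic-spline fixed effect is removed by pooled
  OLS — the covariate is constant within a pair, so residualisation
  preserves the paired structure exactly — and the closed form is applied
  to the residuals.

Confidence intervals are percentile intervals from a cluster
nonparametric bootstrap (default 2,000 resamples, fixed seed), resampling
patients rather than targets so that multiple vessels and frames per
patient do not understate the uncertainty; the cluster variable is an
option. An adjusted-vs-unadjusted comparison is called significant only
when the two CIs are disjoint. ICC interpretation bands: < 0.50 poor,
0.50–0.75 moderate, 0.75–0.90 good, > 0.90 excellent.

*Heterogeneity across calcium strata*: each stratum ICC is Fisher
z-transformed with `se = CI width on the z scale / (2 x 1.96)`; Cochran's
Q with inverse-variance weights gives a chi-square p on G - 1 df, and the
DerSimonian–Laird tau^2 is reported alongside. With two strata this
reduces exactly to the two-sample z-test on the z scale.

*Restricted cubic splines*: Harrell's truncated-power construction
(unnormalised), k - 1 columns including the linear term, knots at the
conventional quantiles (0.10/0.50/0.90 for k = 3; 0.05/0.275/0.50/0.725/
0.95 for k = 5), linear beyond the outer knots with continuous first and
second derivatives everywhere. Three knots serve segment- and
lesion-level adjustment, five the frame level.

## Interaction models

Segment- and lesion-level outcomes are modelled by proportional odds
(cumulative logit) with every distinct observed outcome value its own
category — semiparametric ordinal regression that imposes no binning and
is invariant to monotone relabelling of the outcome. The design is an RCS
in the CTA value, plus an RCS in the CTA calcium area when adjusted, plus
a single product of the two linear terms when the interaction is tested;
keeping the interaction at 1 df preserves power at lesion-level sample
sizes. The likelihood is maximised by L-BFGS with analytic gradients in a
monotone cutpoint parameterisation (`alpha_j = alpha_0 + sum exp(d_i)`),
with design columns standardised internally — the cubic spline columns of
skewed covariates otherwise span several orders of magnitude and the
ill-conditioned problem can stall short of the optimum, which would bias
likelihood-ratio statistics. The full model is warm-started at the nested
optimum so the LRT statistic is nonnegative by construction; coefficient
standard errors come from the numerically differentiated observed
information. The interaction p-value is the 1-df LRT. Frame-level
outcomes use OLS with the same design (5-knot splines) and
subject-clustered standard errors — subjects contribute hundreds of
frames, and the interaction test is a cluster-robust Wald F. Difference
curves evaluate predicted NIRS-IVUS minus CTA on a calcium grid (1st–99th
percentile of the training calcium, 50 points) at the CTA quartiles, with
out-of-range calcium clipped and warned; for the ordinal model the
prediction is the modelled median (smallest category whose cumulative
probability reaches 0.5).

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, at
configurable scale. True log vessel area is `mu + b_subject + AR1(rho,
sd)` (defaults: mu = 2.55 so vessel ~ 12.8 mm^2; subject SD 0.35; AR(1)
coefficient 0.9 so lesions are contiguous, as the lesion rule requires);
plaque fraction is a logistic-scale analogue. Calcium is a two-state
Markov chain along the pullback (stationary zero fraction 0.6,
stay-probability 0.92) with gamma-distributed run levels — zero-inflated,
persistent, capped below the plaque area. Measurements multiply truth by
lognormal noise (residual SD 0.08 on the log scale) and, for CTA, by
`exp(delta0 + delta1 x ca_area)` applied to the lumen and plaque areas
separately (defaults delta0 = -0.45, delta1 = +0.04 for plaque;
-0.28/-0.01 for the lumen): CTA underestimates plaque most where calcium
is absent, with the deficit shrinking — and the lumen deficit growing —
as calcium accumulates, and all biases scale with vessel size. Lipid and
calcium arcs are Markov on/off patches with slowly drifting centre and
width. The "paper-like" preset (64 subjects x 3 vessels x 120 frames at
0.5 mm) reproduces the cohort dimensions of the motivating study design
(~23,000 matched cross-sections); "null" switches every bias off;
"high-calcium" makes calcified frames the rule rather than the exception.

Two focused simulators serve the statistical components.
`two_way_table` draws balanced two-way data with known variance
components; because the modality factor has only two levels, its variance
has a single degree of freedom, and a random draw would make the
realised component — and hence the recoverable ICC — swing wildly between
cohorts; by default the two modality effects are therefore set to
+/- sigma_m / sqrt(2), whose sample variance is exactly sigma_m^2, making
the analytic ICC the per-cohort target (a flag restores random draws).
`interaction_sample` generates `nirs = cta + gamma x ca x cta + noise`
with lognormal CTA values and zero-inflated gamma calcium; only the
outcome is rounded (default 0.1) to mirror reported measurement precision
and bound the ordinal category count — rounding the predictors too would
misalign the outcome grid with the predictors and masquerade as
lack-of-fit in the interaction score.

What passing tests show — and what they do not: the simulations validate
the estimators, test calibration and the pipeline plumbing under the
generative assumptions above (multiplicative noise, smooth pullbacks,
logistic/normal error shapes). They cannot certify behaviour under real
co-registration error, reader disagreement, chemogram artefacts or
non-multiplicative CTA bias, none of which the generator models.

## Problem sizes and numerics

Default analysis runs use 2,000 bootstrap resamples; the shipped
acceptance checks use 200–500 resamples and cohort-scale replicates
(1,000 null replicates at n = 400 for the ordinal test, 100 coverage
replicates at 500 subjects), sizes chosen to keep a full verification run
in minutes on one core while leaving Monte-Carlo error well inside the
asserted tolerances. Variance estimates are floored at zero; ICCs are
clipped to [-1, 1]; quantile-regression fits cap iterations at 2,000;
degenerate inputs (all-equal differences, all-zero strata, sub-4 mm
segments) return defined values with warnings rather than failing, and
genuinely impossible requests (a single frame for a volume, zero-width
CIs in the heterogeneity test) raise typed errors.

## Known limitations

- The remodelling-index and reference-segment conventions are declared
  policies, not community standards; alternative anchors change lesion
  geometry results.
- The frame-level adjusted ICC uses residualisation rather than a joint
  REML fit (see above); for covariates that are constant within a pair
  the two agree closely, but a covariate varying within a pair would
  require the mixed-model route.
- The proportional-odds likelihood-ratio interaction test assumes
  independent observations; segment- and lesion-level records from the
  same patient are treated as independent (a cluster-robust alternative
  exists only for the OLS route).
- No image-level simulation: HU classification operates on
  caller-supplied samples, and chemogram physics is not modelled.
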