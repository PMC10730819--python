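# Methods

## Model and estimands

`mrkit` works in the standard two-sample summary-data MR setting. For SNP
j, let γ_j be its effect on the exposure (estimated with standard error
s_Xj in one study) and Γ_j its effect on the outcome (s_Yj, from an
independent study; log-odds for binary traits). Under the three
instrumental-variable assumptions — relevance (γ_j ≠ 0), independence from
confounders, and exclusion (no path to the outcome other than through the
exposure) — each SNP identifies the causal effect θ through the Wald ratio
Γ_j/γ_j, and the estimators below combine these ratios with different
robustness trade-offs:

* **IVW** is the weighted least-squares slope of Γ on γ through the
  origin, weights 1/s_Yj². The *fixed-effect* SE is (Σγ_j²/s_Yj²)^(−1/2);
  the *multiplicative random-effects* (MRE) SE multiplies it by
  max(1, σ̂), with σ̂² the weighted residual variance on J−1 df. The
  max(1, ·) floor means MRE is never narrower than fixed. Default mode is
  MRE for J ≥ 4 and fixed below; both are available explicitly.
* **MR-Egger** frees the intercept after orienting all SNPs to γ_j ≥ 0;
  the intercept estimates average directional pleiotropy under the InSIDE
  assumption (pleiotropy independent of instrument strength), the slope
  remains a causal estimate. Inference uses a t distribution with J−2 df
  and the same max(1, σ̂) overdispersion floor: with few instruments the
  normal approximation is anti-conservative for the intercept test.
* **Weighted median**: per-SNP ratios are ordered and the piecewise-linear
  weighted empirical CDF (knots at cumulative weight minus half the SNP's
  own weight, normalized) is interpolated at 0.5. Weights are the
  first-order inverse variances γ_j²/s_Yj². The SE comes from a seeded
  parametric bootstrap (default 1000 resamples of both effect vectors from
  their Gaussian sampling distributions). Consistent while valid
  instruments carry > 50% of the weight.
* **MR-PRESSO** computes each SNP's residual against the IVW fit that
  excludes it, forms the inverse-variance-weighted residual sum of squares,
  and compares it with a parametric null in which outcome effects are
  redrawn as N(leave-one-out prediction, s_Yj). Only outcome effects are
  perturbed; the exposure effects are held at their observed values (the
  observed-data RSS uses the same conditioning, so the comparison is
  like-for-like). Per-SNP contributions get empirical p-values with the
  add-one (r+1)/(n+1) convention (never exactly zero), Bonferroni-corrected
  across the J per-SNP tests at level 0.05/J. Flagged SNPs are removed and
  IVW re-run; the distortion test compares the raw-minus-corrected shift
  against shifts from removing random subsets of the same size. Removal is
  the only automatic action; the distortion p is reported, never acted on.
* **Multivariable IVW** regresses Γ on the J×K matrix of exposure effects
  (no intercept, weights 1/s_Yj²), giving each exposure's *direct* effect.
  SEs use the max(1, σ̂) floor on J−K df, so K = 1 reproduces univariable
  IVW exactly. Conditional instrument strength per exposure is the mean
  squared residual z-score after inverse-variance-weighted regression of
  that exposure's SNP effects on the co-exposures' — a residual-based
  diagnostic in the spirit of conditional F, reported and flagged below 10
  but never auto-dropped.
* **Two-step mediation**: A (exposure→mediator, exposure's instruments)
  and B (mediator→outcome, the mediator's *own* instruments — exposure
  instruments would reach the outcome through both paths and bias B).
  Indirect effect A·B; SE by the first-order delta method
  √(A²se_B² + B²se_A²) — the second-order term se_A²se_B² is omitted, which
  matches the reference coefficient table's printed intervals at printed
  precision (the Monte-Carlo check in the test suite confirms the
  first-order form is within 10% of the exact product-distribution SD at
  these signal-to-noise ratios). The mediated proportion is
  100·|A·B/total|, clipped to [0, 100].

## Numerical and reporting conventions

* Confidence intervals use the fixed 1.96 normal multiplier everywhere;
  only p-values switch to t references where stated (Egger).
* Thresholds are strict inequalities: p < 5×10⁻⁸, r² < 0.001, F < 10.
* Clumping is greedy by ascending p-value with ties broken
  lexicographically by SNP id, so the output is invariant to input order.
* Harmonization drops palindromic SNPs unconditionally — no
  allele-frequency rescue at intermediate EAF; EAF is carried for reporting
  only and may be missing. Matching is by SNP identifier; duplicated ids
  are rejected rather than disambiguated.
* Mediated-proportion CI: the indirect effect's normal CI is pushed
  through the ratio at fixed total; when that CI spans zero the lower
  proportion bound is 0, otherwise both bounds are |bound/total|·100,
  sorted, clipped to [0, 100]. A full bivariate delta-method CI (using the
  total's SE as well) is available via `method="bivariate"`. When indirect
  and total effects disagree in sign the result is flagged as inconsistent
  mediation and the proportion remains a magnitude — this reproduces the
  reference table's convention (e.g. DBP: indirect +0.18 against total
  −0.57 reported as 31.48%).
* Empirical p-values in MR-PRESSO are (r+1)/(n+1); n_sim below 1000 is
  rejected.
* Every stochastic routine takes an explicit seed; the pipeline derives
  per-pair seeds from the run seed and a CRC of the pair label, so one
  failing pair never shifts another's random stream.

## Reference coefficient table

`mrkit.datasets.longevity_mediation_coefficients()` carries the published
PM2.5 → mediator → longevity direct effects (A, B), total effects, and the
reported mediation effects/proportions at their printed precision; SEs are
recovered from the CI half-widths. Recomputing A·B reproduces the reported
mediation effect at two decimals for 8 of 12 rows. The remaining four
(angina at both percentiles, DBP 99th, hypercholesterolaemia 99th) differ
by up to ~0.01 — e.g. angina 90th prints A = 0.045, B = −0.36 and a
mediation effect of −0.014, while 0.045 × −0.36 = −0.0162 — consistent
with those rows having been computed from unrounded upstream estimates.
They are checked at ±0.01 absolute and not forced to match. The direct
effects of continuous mediators appear as log-transformed odds ratios
(DBP A = −2.65 = ln 0.07), and binary-trait effects as log-odds
(hypertension A = 0.081 ≈ ln 1.08).

## Synthetic data: what it emulates and what it does not

The generator works at the summary level: γ_j ~ N(μ_γ, σ_γ), observed
exposure effects add N(0, s_X) noise, and outcome effects follow
Γ_j = θγ_j + α_j (plus b·aγ_j when a mediator chain is configured) with
N(0, s_Y) noise, independent across the two samples (no overlap; an
overlap knob is deliberately out of scope). Pleiotropy modes: `balanced`
(zero-mean α), `directional` (constant or N(mag, sd)), and
`inside_violating` (α correlated with γ), each restrictable to a fraction
of instruments. Defaults — J = 30 instruments, γ ~ N(0.25, 0.08),
s_X = 0.02 (mean per-SNP F ≈ 150), s_Y = 0.05, θ = 0, no pleiotropy — are
the package's standing "well-powered, clean study" conditions; SEs can
alternatively be derived from nominal sample sizes as 1/√n. Study bundles
(`simulate_study`) add mediator-specific instruments and multiple outcomes
so the two-step pipeline can be exercised end to end.

What passing tests on these data show: correct estimator algebra,
calibrated uncertainty under Gaussian sampling with known SEs, and the
advertised robustness orderings (weighted median vs IVW under 40% invalid
instruments; Egger intercept recovery under InSIDE). What they do not
show: behaviour under LD misspecification, winner's-curse bias from
selecting instruments in the same sample that estimated them, sample
overlap, non-Gaussian effect distributions, or binary-trait
non-collapsibility — real-data concerns outside the generator's scope.

## Test and benchmark problem sizes

Operating-characteristic checks use: IVW recovery J = 50, θ = 0.2, 500
replicates (bias < 5% of θ, coverage in [92%, 98%]); type-I error 5000
null replicates at level 0.05 against the exact binomial 99% band —
computed with fixed-effect IVW, which is the exactly calibrated test under
the generator's homogeneous null (the MRE max(1, σ̂) floor is conservative
by construction and would sit below the band); Egger intercept recovery
with constant α = 0.05 at J = 100 over 500 replicates; MR-PRESSO
sensitivity/specificity over 200 replicates at n_sim = 1000 with a planted
offset of 10× the median |Γ|; MVMR (0.3, 0.0) recovery over 300 replicates
with s_X = 0.005 so measurement-error attenuation (~0.4% of the residual
signal) is negligible against the Monte-Carlo band; the delta-method SE
against a 10⁶-draw product-distribution oracle; and end-to-end chain
recovery of the 66.7% mediated proportion on a 40+40-instrument study
bundle. These sizes keep the whole suite at a few minutes on one CPU while
leaving each band comfortably wider than its Monte-Carlo error.

## Known limitations

* No correlated-instrument (generalized) IVW: the LD matrix is used for
  clumping only, and clumped panels are treated as independent.
* No mode-based estimators, Steiger filtering, MVMR-Egger, or
  weak-instrument-robust MVMR.
* The Wald-ratio SE is first order (ignores s_X); fine for strong
  instruments (the second-order form is kept as a test oracle, which
  agrees within 5% at F > 100).
* MR-PRESSO perturbs outcome effects only; reference implementations that
  also redraw exposure effects will give slightly different global p-values
  at weak instrument strength.
* Mediators are treated one at a time (no multiple-mediator joint
  decomposition, no difference-in-coefficients estimator).
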