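# Methods

This note documents the statistical models implemented in `mrmediate`, the
assumptions behind them, the synthetic-data generator used for validation,
and the numerical and design choices that were genuinely open.

## Instrument selection and harmonization

Instruments for a trait are the SNPs with association p < 1e-5, pruned by
greedy LD clumping (keep the smallest-p SNP, remove candidates on the same
chromosome within 10,000 kb whose squared correlation exceeds 0.001, repeat)
and screened for strength with the single-SNP approximation F = (β/se)².
SNPs with F < 10 are removed as weak instruments.  A literal variant of the
strength screen, β/se², is available behind `f_literal`; it is not a
standard F statistic and is off by default — the conventional (β/se)² is
what the threshold of 10 belongs to.  Ties in p-value break by (chromosome,
position); SNPs absent from the LD matrix are treated as independent and
logged, so partial LD panels are usable.

Harmonization aligns outcome effects onto the exposure's effect allele.
Palindromic pairs (A/T, G/C) are always dropped — no allele-frequency
rescue — because strand cannot be resolved for them.  Swapped alleles
(directly or after strand complement) negate the outcome beta; any other
configuration is dropped as ambiguous.  Instruments missing from the
outcome are dropped with a log entry; proxy-SNP search would require an
external LD reference panel and is deliberately out of scope.
Harmonization never changes the magnitude of any kept effect, and kept +
dropped always equals the input count.

## Estimators

All estimators consume the harmonized arrays (γ̂ⱼ, σ_Xⱼ, Γ̂ⱼ, σ_Yⱼ) and are
exposed as scikit-learn-style classes with `fit` and trailing-underscore
attributes, so they compose with sklearn tooling; module functions wrap
them.

**Wald ratio.** Γ̂ⱼ/γ̂ⱼ with first-order SE σ_Yⱼ/|γ̂ⱼ|.  The second-order
SE (adding Γ̂²σ_X²/γ̂⁴) is available by flag but off by default, matching
common practice.  The first-order form ignores exposure-side noise (the
NOME approximation); see *Calibration regimes* below for when that matters.

**IVW.** Weighted mean of ratios with weights 1/se², identical to
origin-constrained WLS of Γ̂ on γ̂ with weights 1/σ_Y² (verified to 1e-10
against `statsmodels` WLS).  The multiplicative random-effects SE scales
the fixed-effect SE by √max(1, Q/(J−1)) and is the headline variant, the
default of the widely used implementations; fixed-effect is reported
alongside.

**MR-Egger.** WLS with intercept, after orienting all pairs to γ̂ⱼ ≥ 0
(required for the intercept to be interpretable as average directional
pleiotropy; estimates are invariant to per-SNP allele re-coding).  SEs are
scaled by the overdispersion factor floored at 1; inference uses t with
J−2 df.

**Weighted median.** Ratios ordered ascending; with normalized weights wⱼ
the estimate interpolates the ratio at cumulative-midpoint 1/2.  SE from a
parametric bootstrap (γ̂, Γ̂ resampled from their Gaussians; default 1000
draws, seeded).  The bootstrap scheme is behavioral, not a bit-for-bit
match of any particular package.

**Modes.** Gaussian-KDE mode of the ratios, unweighted (simple) or
inverse-variance weighted.  Bandwidth: φ · 0.9 · min(sd, MAD/0.6745) ·
J^(−1/5) with φ = 1 by default; density evaluated on a 512-point grid over
the ratio range ± 3 bandwidths; degenerate inputs (all ratios equal) return
the common value.  SE by the same parametric bootstrap.

**BWMR.** Hierarchical model γ̂ⱼ ~ N(γⱼ, σ_Xⱼ²),
Γ̂ⱼ ~ N(βγⱼ + αⱼ, σ_Yⱼ²), γⱼ ~ N(0, σ₀²), αⱼ ~ N(0, τ²).  The fit
alternates (i) posterior updates of the latent γⱼ and of (β, τ², σ₀²) and
(ii) robustness-weight updates wⱼ = exp(−max(0, tⱼ²−1)/2) from
standardized residuals, initialized deterministically at the IVW
fixed-effect estimate, stopping when |Δβ| < 1e-6 (cap 5000 iterations;
non-convergence is flagged and the last iterate returned).  Two choices
here deserve explanation:

- *Weights act on the outcome equation only.*  Pleiotropy is a violation of
  the outcome model, not of the exposure measurement.  Down-weighting a
  SNP's entire likelihood lets its latent γⱼ collapse to the prior, which
  inflates the residual tolerance and resets the weight — a period-2
  oscillation we observed directly.  Restricting the weight to the Γ̂ term
  is stable and keeps genuine outliers excluded.
- *Standard error.*  The estimating equation uses the redescending score
  ψ(t) = w(t)·t, so the naive curvature SE understates the sampling
  variance.  We apply the M-estimation correction
  E[w]·E[ψ²]/E[ψ′]² ≈ 1.233 (computed by quadrature under t ~ N(0,1) at
  import).  With it, empirical type-I error at nominal 0.05 is ~0.05
  across 1000 null replicates; without it, ~0.10.

Under the robust weighting the expected weight for a clean SNP is ~0.87
and the median weight is 1; individual clean SNPs routinely receive
weights below 0.9 (any |t| > 1.1 does), which is intended behavior of the
weight function, not a sign of contamination.

## Diagnostics

**Cochran's Q** over the Wald ratios with weights 1/se², χ²(J−1).  The sum
of per-SNP contributions reproduces Q to 1e-8.

**Egger intercept test** re-exposes the regression intercept as a
directional-pleiotropy gate.

**MR-PRESSO.**  Observed statistic: RSS = Σⱼ wⱼ(Γ̂ⱼ − β̂₍₋ⱼ₎γ̂ⱼ)² with
leave-one-out origin-WLS slopes and wⱼ = 1/σ_Yⱼ².  Null distribution from
parametric datasets γ*ⱼ ~ N(γ̂ⱼ, σ_Xⱼ), Γ*ⱼ ~ N(β̂₍₋ⱼ₎γ̂ⱼ, σ_Yⱼ), each
refit with its own leave-one-out slopes.  The global p-value uses the
plus-one estimator (smallest reportable value 1/(n_sim+1)).  Per-SNP
outlier p-values are plain empirical tail proportions (which may be 0),
Bonferroni-adjusted over J: a plus-one floor here would make detection at
level α impossible whenever n_sim < J/α, defeating the test.  When
outliers exist, the outlier-corrected IVW estimate is returned together
with a distortion test (observed shift of the estimate vs shifts from
removing random same-size subsets).  A known property of the construction:
for a very high-leverage outlier, the leave-one-out centers of the *other*
SNPs absorb part of the contamination, which inflates the outlier's own
simulated null and reduces power; detection of typical-leverage outliers
(10 outcome-SEs) exceeds 99% at n_sim = 500.

**Leave-one-out** re-runs IVW excluding each SNP in turn.

## Two-step mediation

Each leg (a: exposure→mediator, b: mediator→outcome, c: exposure→outcome)
is an independent univariable MR with its own instrument selection — not
multivariable MR; this matches the two-step design and is a documented
limitation (b is unadjusted for the exposure).  The decomposition is
indirect = a·b, direct = c − a·b (exact identity by construction),
proportion = a·b/c.  First-order delta SEs by default (second-order by
flag); the proportion's CI uses the delta method on the ratio treating the
three estimates as independent, justified by the two-sample, three-cohort
setting.  A proportion is flagged undefined when c = 0 and "inconsistent
mediation" when the indirect and total effects disagree in sign —
reported, but not interpretable as a share.  Proportions are reported as
percentages; recomputing the five published decompositions from their
printed coefficients reproduces the printed indirect effects at 3 dp and
the printed proportions to within rounding of the source's own mixed
precision (which divided the *rounded* indirect by the *rounded* total).

## Screening rules

A pair is *significant* when IVW and BWMR are both below α = 0.05 with
concordant signs; heterogeneity (Q), Egger-intercept or MR-PRESSO global
p below α exclude the pair outright.  "Positive association" for the
third-method rule means p < α with sign concordant to IVW (a
directional-consistency-only variant is available).  Reverse screening
instruments the outcome and flags exposures with reverse IVW p < α.  A
mediation candidate requires: the exposure→outcome leg to pass the
three-method rule (IVW + BWMR + ≥1 of Egger/median/modes), no reverse
flag, clean diagnostics on all three legs, IVW+BWMR concordance on both
mediation legs, and sign-consistency of a·b with c.  No multiple-testing
correction is applied by default (nominal-α reporting); a
Benjamini–Hochberg option exists.

Because the candidate rule stacks nine exact-level 5% gates (three
diagnostics × three legs), a fully clean true-mediation triplet is
falsely excluded in roughly 20–25% of runs (per-leg gate union ≈ 9%,
measured over 120 clean legs).  This compounding is a property of the
workflow itself, not of any single test: negative controls are rejected
essentially always, while positive-control selection plateaus near
75–85% and cannot reach 95% without raising the gates' thresholds.

## Synthetic data

The generator works directly on the summary-statistic scale — two-sample
MR consumes nothing else — with continuous-liability log-odds outcomes (no
case/control ascertainment) and no cohort overlap.  Structure: J exposure
instruments with effects γⱼ on the exposure, a·γⱼ on the mediator and
(c′ + a·b)·γⱼ + αⱼ on the outcome (αⱼ the pleiotropic offset, present
with probability π, drawn N(μ_α, τ²)); and K mediator-specific
instruments δₖ affecting the mediator, with b·δₖ on the outcome and no
exposure effect.  The mediator-specific set is what makes the b leg
identifiable: without it, MR of mediator on outcome over the exposure's
instruments estimates c/a, not b.  Estimates add N(0, se²) noise with
se = 1/√(2p(1−p)n); allele frequencies are uniform on [0.05, 0.5];
p-values are two-sided Gaussian; same seed ⇒ byte-identical output.

Effect sizes are physical: their scale is set so the expected single-SNP
F is ~1 + `mean_instrument_f` (default 30) in a reference cohort
(`f_reference_n`, default the exposure GWAS size), so larger cohorts give
proportionally stronger instruments, as in real data.  Default cohort
sizes mirror the study the pipeline is modeled on: exposure n = 7738
(microbiome GWAS), mediator n = 3757 (immune phenotypes), outcome
n = 330,690 (biobank disease endpoints); default J = K = 150, the order
of magnitude genome-wide selection at p < 1e-5 yields.

LD matrices are block-diagonal AR(1) (r = ρ^|i−j| within a block), exact
and positive semi-definite; harmonization artifacts (allele flips with
beta negation and frequency reflection, palindromic rewrites) are injected
by a separate, logged operation whose flip is an involution.

### What the generator does not emulate

Real LD panels and proxy lookup, haplotype structure, binary-trait
case/control sampling, sample overlap, population stratification,
X-chromosome effects, and winner's-curse-inducing discovery/replication
splits.  Passing tests therefore demonstrate correctness of the estimators
and workflow under the stated generative model, not robustness to every
artifact of real GWAS.

## Calibration regimes and problem sizes

The first-order Wald SE ignores exposure-side noise; its adequacy requires
c²σ_X² ≪ σ_Y².  At the generator's defaults (expected F ≈ 31), that term
inflates Cochran's Q by a factor 1 + c²σ_X²/σ_Y², and for a large causal
effect with comparable cohort sizes the inflation is substantial — the
classical "clean data ⇒ Q/(J−1) ≈ 1" property is a strong-instrument
(NOME-regime) property.  Calibration, recovery and coverage studies
therefore simulate cohorts of 3×10⁵–10⁷ with effect sizes referenced to
the 7738-sample cohort, i.e. single-SNP F in the hundreds-to-thousands,
the regime the estimators assume.  Null-calibration suites use the
designed instrument set directly rather than re-selecting per replicate,
since per-replicate selection conditions on the data in a way the sampling
theory does not model.

Problem sizes, chosen to characterize each property with Monte-Carlo error
well below the asserted margins: type-I error at 1000 replicates (J = 100);
two-step recovery and CI coverage at 200 replicates of the headline
scenario (a = 0.24, b = −0.27, c′ = −0.90, J = 150, n ≈ 3×10⁵);
MR-PRESSO power and BWMR-vs-IVW bias at 200 replicates (n_sim = 500);
end-to-end screening controls at 40 positive + 40 negative triplets.

## Known limitations

- No proxy-SNP lookup; instruments missing from the outcome are dropped.
- No multivariable MR, Steiger filtering, radial MR, or contamination-
  mixture estimators.
- BWMR is a faithful implementation of the stated hierarchical model and
  weighting contract, validated behaviorally (recovery, robustness,
  calibration); it is not claimed to match any external package's exact
  variational schedule.
- First-order Wald SEs understate uncertainty for weak instruments with
  large causal effects (see calibration regimes).
- The product-method mediation SE treats the three legs as independent;
  overlapping cohorts would violate this.
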