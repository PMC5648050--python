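# Methods

## Model

For a two-arm trial (open repair `O`, endovascular `E`) with a utility
outcome observed for responders only, the pattern-mixture factorisation
writes each arm mean as

    mean_a = (1 − π_a) · E[Y | observed, a] + π_a · E[Y | missing, a]
           = μ_a + π_a · δ_a ,

with μ_a the responders' mean, π_a the missingness proportion, and
δ_a = E[Y | missing, a] − E[Y | observed, a] the sensitivity parameter. The
estimand is Δ = (μ_E + π_E δ_E) − (μ_O + π_O δ_O). δ_a is structurally
unidentifiable: nothing in the observed data constrains it, which is why it
is given an elicited prior rather than estimated.

Assumptions: outcomes within the observed pattern of each arm are modelled
as normal; missingness is independent across patients; the elicited beliefs
refer to patients exchangeable with the trial's, conditional on the anchor
description shown to the experts.

## From elicitation to priors

Experts answer on the utility × 100 scale (−20..100). With anchor scores
(the displayed observed-patient score per arm) `A_O`, `A_E`:

* marginal offsets: δ_a ~ N((mode_a − A_a)/100, (sd_a/100)²);
* correlation, from the conditional answer about the E-arm score given a
  stated O-arm score `v`: for a bivariate normal,
  E[δ_E | δ_O = v'] = m_E + ρ (s_E/s_O)(v' − m_O) and
  SD[δ_E | δ_O = v'] = s_E √(1−ρ²), so ρ can be read off either the
  conditional-mean displacement (`mean_shift`, signed) or the conditional-SD
  shrinkage (`sd_ratio`, magnitude only). `mean_shift` is the default
  because it uses exactly the quantity the conditional question displaces;
  `sd_ratio` is retained as a robustness check, with its sign taken from the
  mean-shift direction unless overridden. When the three answers are
  mutually consistent with one bivariate normal the two agree in absolute
  value (property-tested). Values outside [−1, 1] are clamped with a
  warning; conditioning exactly at the marginal mean is an error
  ("uninformative conditioning point").

Anchors are required configuration with no default: they are facts about
what the experts were shown, not modelling choices.

Elicited normals are used untruncated even though the scale is bounded; a
warning is raised when more than 5% of a prior's mass falls outside the
feasible offset range [−1.2, 1] on the utility scale. Near-total-uncertainty
responses (elicited SD above 40 scale units by default) are flagged, never
silently dropped; `exclude_flagged` applies the exclusion explicitly and
returns the removed ids.

## Pooling

Equal-weight linear pooling of K expert priors yields the mixture
f(δ) = (1/K) Σ_k f_k(δ). Mixture moments are exact:
mean = Σ w_k m_k, cov = Σ w_k (Σ_k + m_k m_kᵀ) − m mᵀ. The community of
priors consists of the all-expert pool, role-subgroup pools, and the two
extreme individuals, defined operationally as the extrema of the prior mean
of (δ_E − δ_O) — the most sceptical expert leans furthest toward open
repair for the missing patients, the most enthusiastic furthest toward the
endovascular arm. The selection rule is documented here because the notion
of "extreme" is not unique; an explicit expert id can always be supplied
instead.

## Estimators

**Moment estimator.** Δ̂ plugs prior means into the Δ formula; the variance
adds the independent contributions
V(μ_E) + π_E² V(δ_E) + V(μ_O) + π_O² V(δ_O) and subtracts
2 π_E π_O cov(δ_E, δ_O) when the pooled prior correlates the offsets. π is
treated as known (no V(π) term). Confidence intervals are Δ̂ ∓ z·SE with
z = 1.96.

**Bayesian model.** Observed outcomes: y_i ~ N(μ_a, σ_a²) per arm, with
μ_a ~ N(0, 10⁶) and σ_a² ~ InverseGamma(10⁻³, 10⁻³). The inverse-gamma was
chosen over a half-normal/uniform SD prior so that every full conditional
is an exact draw (pure Gibbs, no Metropolis step); with ≥ 2 observations
per arm the two weak priors are numerically indistinguishable here.
(δ_O, δ_E) are drawn from the pooled mixture via a latent categorical
component indicator; since δ does not enter the likelihood these are exact
independent prior draws each iteration — the posterior of δ *is* the prior,
and a two-sample test against direct pool samples verifies the sampler
honours this. π_a defaults to the plug-in proportion (matching the moment
variance, which has no V(π) term); `pi_mode="beta_binomial"` draws
π_a ~ Beta(1 + n_miss, 1 + n_obs) to propagate missingness-proportion
uncertainty. Arm-specific residual variances are the default (the arms
differ clinically); a pooled-variance option exists. Optional covariate
adjustment adds centred linear terms with weak normal priors, sampled
jointly with the arm means by weighted-least-squares conditionals; centring
makes μ_a the adjusted arm mean at the average covariate profile.

When built from arm summaries instead of patient data, the likelihood for
μ_a is N(μ̂_a, se²), giving independent exact posterior draws — this is the
configuration in which the Bayesian posterior of Δ has the moment
estimator's closed form, used as a conjugacy cross-check.

Sampler defaults: 4 chains, 2000 warm-up + 2000 kept iterations, seed
mandatory. Split-R̂ and bulk ESS (via arviz) are computed for all continuous
monitored parameters; any R̂ > 1.05 blocks reporting unless `force=True`.
Credible intervals are equal-tailed 2.5/97.5 percentiles. Display rounding
is 3 dp (2 dp where the closed-form worked example is quoted, matching how
such examples are conventionally printed).

**Comparators.** `mar_fit` fixes both offsets at zero (MAR given the
modelled covariates); `complete_case=True` additionally drops covariate
adjustment. `tipping_point_scan` treats each grid point (δ_O, δ_E) as known
(SD 0) and flags where the CI first excludes zero and where the point
estimate reaches the MCID.

## Synthetic data

**Trials.** Outcomes are normal per arm; missingness is logistic in the
*true* outcome: P(missing | y) = expit(a + b·y), the canonical MNAR
mechanism for "sicker patients return fewer questionnaires" (b < 0).
Defaults: 200 patients/arm, true means 0.67/0.74 (Δ = 0.07), SD 0.25,
b = −1 with intercepts calibrated by quadrature to ≈ 24%/18% missingness,
implying generating offsets ≈ −0.06 per arm — magnitudes chosen to emulate
a realistic post-surgical QoL trial with ~20% missing follow-up. The
generating δ_a are computed by 80-node Gauss–Hermite quadrature
(`truth_delta`), not stored approximations, and `calibrate_missingness`
root-solves (a, b) per arm to hit any requested (δ, π) — used to build
trials whose truth is an exact draw from a prior ("matched truth"), which
turns the coverage test into a proper Bayesian calibration check. An
optional covariate enters the outcome linearly and can also drive
missingness (an MAR mechanism) for testing the MAR comparator.

**Panels.** Each synthetic expert holds an exactly bivariate normal belief
over (δ_O, δ_E); their three recorded answers are the analytic marginals
and the analytic conditional at a point one elicited SD from the open-arm
mode, so prior construction inverts the generator to machine precision.
Expert means are truncated (by rejection) to modes in [−15, 95] and
elicited SDs clipped to [0.02, 0.28] utility units with |ρ| ≤ 0.9, which
guarantees every derived answer — including the conditional mode, displaced
toward the scale centre — stays on the −20..100 scale. Panel defaults
(26 experts: 9 nurses, 17 doctors; offsets −0.04/−0.01; between-expert SD
0.16; within-expert SD 0.15; ρ = 0.3; anchors 65/73) emulate a panel of
clinicians who believe non-responders fare slightly worse, nurses slightly
more optimistic than doctors.

What the generators do **not** emulate: skewed or multimodal true outcome
distributions (EQ-5D utilities are left-skewed with a ceiling at 1),
item-level EQ-5D responses, longitudinal dropout, mortality-linked
missingness, or experts whose beliefs are not normal. Passing tests
therefore demonstrate internal correctness of the estimators under the
stated model, not robustness to those real-data features.

## Numerical choices and scaled-down sizes

* Mixture sampling adds 10⁻¹⁵ to covariance diagonals before Cholesky so
  degenerate (point-mass) components are valid inputs.
* Pool weights must sum to 1 within 10⁻¹²; pooled covariance is
  symmetrised after accumulation.
* The moment-estimator variance is floored at 0 against rounding when a
  strongly correlated pool nearly cancels the cross-term.
* Density strips guard degenerate draws (range < 10⁻¹²) by emitting a
  single saturated cell; the default Δ grid is [−0.3, 0.4] with 701 points.
* Stochastic tests fix seeds and use 3-SE Monte-Carlo tolerances; where a
  test aggregates many simultaneous z-statistics the 3-SE level is applied
  family-wise (Šidák-adjusted max-|z|), which is the joint form of the same
  per-quantity tolerance.
* Test problem sizes are chosen for a single-CPU desk run: coverage uses
  200 replicates of 150 patients/arm with 2 chains × (400 + 800)
  iterations; Monte-Carlo cross-checks use 2×10⁵–10⁶ draws.

## Known limitations

* The Bayesian likelihood is normal; with heavily skewed utilities the
  posterior of μ_a relies on the CLT through the arm sample sizes.
* `mean_shift` correlation extraction is exact only if the expert's answers
  are mutually consistent with one bivariate normal; inconsistent answers
  are clamped into [−1, 1] rather than reconciled.
* Equal-weight pooling makes no attempt at performance-based expert
  weighting or behavioural consensus; subgrouping is the only weighting
  mechanism.
* The package analyses one endpoint at one time point; QALY construction,
  subgroup effect modification and multiple-time-point elicitation are out
  of scope.
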