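# Methods

## The battery and its measures

The package analyses a one-shot economic-game battery for two-group
(case-control) designs. The tasks and their scales:

| task | record | scale |
| --- | --- | --- |
| SVO slider | 15 items × choice of 9 payoff options | option index 1–9 |
| Dictator game | one allocation of 10€ | 0–10 € |
| Ultimatum game | accept/reject six offers | offers 1–6 €, binary |
| Minimum acceptance | smallest acceptable offer | 0–10 € |
| Fairness ratings | 11 hypothetical splits of 10€ | Likert 1–9 |
| Joint payoff evaluation (JPE) | 121 payoff pairs (−50…50 step 10)² | Likert 1–8 |

Raw JPE instruments anchor 1 = very good; the analysis scale used
throughout this package is reverse-coded (larger = better) so that
regression weights on utility features are positive. The loader for real
data exposes `reverse_code_jpe` for this; the synthetic generator emits
analysis-ready ratings directly.

## Utility model and per-subject fitting

The core preference model is the Fehr–Schmidt inequality-aversion utility

    U(x_s, x_o) = x_s − α·max(x_o − x_s, 0) − β·max(x_s − x_o, 0),

with α weighing disadvantageous and β advantageous inequality. Eight
alternative feature maps (selfish, other-regarding, joint gain, total
inequality, inequality & joint gain, Charness–Rabin-style regime split,
max-min, envy-only) complete the nine-model registry; the registry is data
and can be replaced wholesale.

Each subject's grid ratings are z-scored (scale use differs across
subjects; a raw-scale fit is available by flag) and regressed on each
model's features by OLS. Per-subject model evidence is approximated as
−BIC/2 at the Gaussian MLE with k = predictors + intercept + residual
variance. Because any rating scale is an unknown affine transform of
utility, the structural weights are reported as coefficient ratios,
`α̂ = −b_disadv / b_self`, which are invariant to that transform. Constant
rating vectors are flagged degenerate (zero slopes, R² = 0) rather than
rejected, with a small variance floor keeping the evidence finite.

## Group-level model comparison

Fixed effects: log-group Bayes factors, the per-subject log-evidence
differences summed over subjects. Random effects: the variational
Dirichlet-multinomial scheme — responsibilities
`u_sm ∝ exp(L_sm + ψ(α_m) − ψ(Σα))` and counts `α = α₀ + Σ_s u_s` iterated
from a uniform prior (α₀ = 1) until the free-energy change falls below
10⁻⁶ (at most 10⁴ iterations; non-convergence raises with the trace).
Exceedance probabilities come from 10⁵ seeded Dirichlet draws; the Bayes
omnibus risk compares the fitted model's free energy against the
equal-frequency null at prior odds 1:1, and
`PXP = XP·(1 − BOR) + BOR/K`. The two schemes are run separately per
group and can disagree — a model winning by large margins in few subjects
dominates the summed evidence while a model winning modestly in many
dominates the frequency estimate; `select_best` reports both winners with
margins and never breaks exact ties silently.

## Group inference

Welch's t (Satterthwaite df, 95% CI) and the Wilcoxon rank-sum
(asymptotic z with tie correction, no continuity correction — matching the
R conventions common in this literature; `r = |z|/√N`) accept raw vectors
or (M, SD, N) summaries, and the raw route reduces to exact summaries so
both agree by construction. Cohen's d uses the average-variance
standardiser `√((s₁² + s₂²)/2)`: on the bundled published tables this form
reproduces every printed effect size (the df-pooled form does not — e.g.
it gives −0.419 where −0.400 is printed).

The JZS default Bayes factor for the two-sample design places a
Cauchy(0, √2/2) prior on the standardised effect and integrates the
g-prior representation by adaptive quadrature on the log scale
(`N = n₁n₂/(n₁+n₂)`, df `n₁+n₂−2`). Two entry points exist because
published BFs are computed from raw data — i.e. from the pooled-variance
Student t — while printed statistics are typically Welch t values:
`jzs_ttest_bf(t, n1, n2)` takes a t directly, `jzs_ttest_bf(a=…, b=…)`
reconstructs the pooled t from summaries. On the bundled tables the
summary route reproduces the published BF01 values (3.48, 0.91, 0.47);
the printed-Welch-t route gives 3.34, 1.17, 0.65, and
`bf_entry_point_comparison` reports both. The implementation is verified
against an independent quadrature over the noncentral-t marginal.

## Mixed models

Rejection model: logistic with a participant random intercept; fixed
effects are the centered offer (offer − 3.5), the predictor (group with
controls as reference coded 0, or mean-centered dissociality) and their
interaction. statsmodels has no likelihood-based binomial mixed model, so
the marginal likelihood is computed by 25-node Gauss–Hermite quadrature
over the scalar intercept (effectively exact at that order) and maximised
by L-BFGS-B over (β, log σ_b) with a Nelder–Mead polish; Wald SEs come
from the numerical Hessian, t statistics use residual df = n − p, and
odds ratios are exp(b). On a deterministic fixture the fit agrees with
lme4's `glmer(nAGQ = 25)` to ~10⁻⁴ on coefficients and SEs; that oracle is
frozen into the tests and re-run live against Rscript where available.
This quadrature ML is used instead of Laplace or pseudo-likelihood
approximations: for a single random intercept it is the most accurate of
the three at negligible cost. Complete separation (constant outcome)
returns a flagged result instead of crashing; a variance estimate pinned
at the zero boundary is flagged and its SEs are profiled over β only.

Fairness model: Gaussian linear mixed model (statsmodels MixedLM, REML)
with fixed effects group, centered offer (offer − 5), centered offer²,
and the two group interactions — the inverted-U specification. Fewer than
three distinct offers make the quadratic unidentifiable and raise.

## Meta-analysis

Per study, Cohen's d with the pooled-SD standardiser (no small-sample
correction; Hedges-style use can apply it upstream) and
`var(d) = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))`. `aggregate_summaries` combines
condition-level (M, SD, n) through exact sums of squares, so aggregating
then scoring equals scoring the pooled sample. Random-effects pooling is
inverse-variance with τ² by REML (default; bounded scalar optimisation)
or DerSimonian–Laird; `tau2_method="FE"` forces the fixed-effect limit.
Heterogeneity: Cochran's Q, `I² = max(0, (Q − df)/Q)·100` (the convention
of the R `meta` package; metafor's model-based I² differs slightly), and
Q-profile CIs for τ² transformed to I² through the typical within-study
variance. Both estimators reproduce metafor's `rma` output on a fixture
to ~10⁻⁵. A single study passes through with heterogeneity reported as
zero.

## Synthetic cohort: what it emulates and what it does not

Agents carry latent (α, β, noise SD, temperature) plus a 12-item
dissociality trait score (Likert 1–5 items, range 12–60). Choices are
softmax over option utilities (slider, dictator), a logistic acceptance
rule with U(reject) = (0,0) — an equal split, so it carries no inequality
penalty — for the ultimatum game, and affine maps of utility onto the
rating scales for fairness and the JPE grid: anchored at the noiseless
utility extremes of the stimulus set, Gaussian noise added in rating
units, rounded half-up, clamped. A flat utility profile maps to the scale
midpoint.

Defaults are the study-scale conditions: 35 + 50 participants, rating
noise SD 0.5, temperature 1, and identical preference distributions in
both groups (α ~ N(0.8, 0.3) truncated at 0, β ~ N(0.45, 0.15)) with a
group difference only in dissociality (27 ± 7 vs 20 ± 6). The preference
spread follows the classic Fehr–Schmidt population calibration in which a
substantial minority has β ≥ 0.5 (equal splitters) while most do not.

Limitations to keep in mind when reading passing tests: real respondents
are not exact utility maximisers with additive Gaussian rating noise;
response styles (scale anchoring, midpoint avoidance), order effects and
attention lapses are absent; every synthetic cohort is *truly* generated
by the Fehr–Schmidt model, so group-level model selection recovering that
model says nothing about which model real data favour — in particular the
fixed-/random-effects dissociation observed in real cohorts is exercised
here only through constructed evidence fixtures. Dissociality is simulated
independently of the game-playing latents, so null dissociality effects in
the rejection model are the generator's truth, not a prediction.

## Numerical and design choices

- SVO category boundaries (57.15°, 22.45°, −12.04°) and the slider menus
  are the published instrument constants; boundaries are closed on the
  prosocial side. A mean self-allocation of exactly 50 makes the angle
  undefined and raises with guidance.
- Secondary-item ideal points are derived from the menus themselves:
  inequality-averse ideal = argmin |self − other| (ties toward higher
  joint payoff), joint-gain ideal = argmax self + other (ties toward
  lower inequality). The prosocial-motivation index ties at 0.5 are
  assigned inequality-averse.
- Consistency screen (configurable): primary category must be prosocial
  and every secondary choice must lie within one option of one of the two
  prosocial ideals. Published screens of this kind live in study
  supplements; this rule is the package's documented stand-in and is
  logged with its parameters.
- Euro amounts, payoffs and ratings are stored as integers; CSV is the
  single tabular interchange format, JSON for structured results, YAML
  for configuration; every output bundle embeds the config hash and seed.
- Problem sizes used by the validation suite — 85 subjects × 121 trials
  for model selection, 100 subjects for recovery, 200 replicates for the
  mixed-model calibration, 2000 for the Welch type-I check — were chosen
  as the smallest sizes at which the corresponding population claims are
  stable.
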