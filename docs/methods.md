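# Methods

## Data model

Subject-level two-arm right-censored data: per subject a follow-up time
t ≥ 0 (study time, measured from entry), an event indicator δ ∈ {0, 1}
(1 = event, 0 = right-censored) and an arm label with exactly two values,
one designated control. Each arm must contribute at least two subjects and
one event. Zero times are accepted (a censoring at the origin contributes
S(0) = 1 to the likelihood; an event exactly at 0 is rejected because the
Weibull density is degenerate there). The *default horizon* τ_d is the
minimum over arms of each arm's largest observed time — censored times
included — which is the largest τ at which both KM-based RMSTs exist; tied
maxima are resolved by the exact minimum.

## Mixture-Weibull model and fitting

Each arm is modelled as S(t) = Σⱼ pⱼ exp[−(t/λⱼ)^kⱼ] with J ≤ 3
components. One component is an ordinary Weibull; two or three components
reproduce the shapes that defeat proportional hazards: a late-separating
survivor component (delayed effect), a fast-failing plus a late component
(crossing), or a very-long-scale component (effective cure fraction — a
plateau; no explicit cure point mass is used).

The censored log-likelihood Σ δᵢ log f(tᵢ) + (1−δᵢ) log S(tᵢ) is maximized
over the unconstrained parameterization (log λⱼ, log kⱼ, weight logits
with the last component as reference) by L-BFGS-B with numerical
gradients: relative log-likelihood tolerance 1e−9, at most 500 iterations
per start. Starting values use a quantile-split heuristic — times split
into J contiguous quantile blocks, each λ initialized at its block mean,
shapes at 1, weights equal — plus seeded Gaussian jitters (sd 0.5 on the
transformed scale); the best of `n_starts` (default 10) runs is returned.
Box bounds keep log λ within [log t_max − 15, log t_max + 8] and
log k within [−3, 3]; weights are floored at 1e−6 (a weight at the floor
triggers a warning recommending fewer components). Data are sorted before
likelihood evaluation, so the fit is exactly invariant to row order and
deterministic given the seed.

The parameter covariance is the pseudo-inverse of the observed information
(negative Hessian of the log-likelihood), evaluated by central finite
differences (relative step 1e−4) on the transformed scale. Eigenvalues at
or below 1e−10 of the largest are treated as flat directions and excluded
from the inverse; a condition number above 1e10 raises a warning. This
lenient treatment is deliberate: under administrative censoring the scale
of a long-survivor component is only bounded below by the data, giving a
genuinely flat likelihood direction on which the restricted-mean
functional barely depends — discarding the whole covariance there would
disable inference needlessly. The covariance is flagged unavailable (and
delta-method inference disabled) only when no positive curvature exists.

The number of components defaults to 3 but should be set from subject-
matter knowledge when available; AIC/BIC selection over {1, 2, 3} is
provided as an explicit opt-in (`select_components`).

## Restricted means, variances, contrasts

With X = min(T, τ), the RMST is μ(τ) = E X = ∫₀^τ S(t) dt and the
restricted variance var(X) = 2∫₀^τ t S(t) dt − μ(τ)²; its square root is
the restricted standard deviation (RSDST). Both integrals are closed-form
per component via the lower incomplete gamma function,

∫₀^τ t^m exp[−(t/λ)^k] dt = (λ^{m+1}/k) γ((m+1)/k, (τ/λ)^k),  m ∈ {0, 1},

evaluated as the regularized incomplete gamma times the complete gamma for
stability at small shapes (k < 1 makes s = 1/k large).

Sampling variances use the delta method: se² = g′Σg with g the central-
difference gradient (relative step 1e−5) of the functional with respect to
the transformed parameters and Σ the covariance above. The CI for μ(τ) is
truncated to [0, τ]; contrast CIs are not truncated. Contrasts (treatment
vs control, arms fitted independently so variances add):

* difference Δ(τ) = μ₁ − μ₀, normal CI Δ ± z_{1−α/2}·se;
* ratio θ(τ) = μ₁/μ₀, inference on log θ with
  var = var(μ₁)/μ₁² + var(μ₀)/μ₀², CI exponentiated;
* RMTL ratio (τ−μ₁)/(τ−μ₀) — preferable when event rates are low and θ
  hugs 1 — treated identically on the log scale.

p-values are two-sided normal throughout; the sidedness convention is a
package choice, stated here because published analyses do not always
specify theirs.

## KM reference engine

The product-limit fit is delegated to lifelines; the RMST is the exact
area under the resulting step function, with the classical variance
Σᵢ Aᵢ² dᵢ/(nᵢ(nᵢ−dᵢ)) over event times up to τ, Aᵢ the area from t₍ᵢ₎ to
τ. Deaths precede censorings at tied times. When the last at-risk subject
has an event (nᵢ = dᵢ) the undefined term is dropped with a warning —
the convention of the standard RMST software this matches. Requests for
τ beyond the largest observed time raise an error pointing to the
parametric engine; a step-function estimate simply does not exist there.

## Dynamic curves

`build_dynamic_curve` evaluates both engines on a τ grid (default: 100
equally spaced points from τ_d/100 to τ_d) and stores per-arm estimates
plus the difference/ratio (and optionally RMTL-ratio) contrasts with
pointwise CIs. KM entries are absent — not zero — beyond each arm's own
follow-up, and KM contrasts beyond the shorter of the two. The grid may
extend past τ_d up to `extrapolation_factor` × τ_d (default 1.5); longer
grids are clamped with a warning, since parametric extrapolation far past
the data is exactly the kind of confidence this method should not project.
Every grid point is computed independently (no path dependence), so grid
refinement never changes shared values.

Diagnostics: `km_mixture_agreement` summarizes |mixture − KM| RMST per arm
over the shared grid, absolutely and in KM standard-error units (≥ 3
shared points required). `follow_up_adequacy` reports the relative change
of Δ(τ) and θ(τ) over the trailing window (default last 20% of the grid;
plateau flag when below 1%) and the grid point nearest any zero crossing
of Δ — where θ and the RMTL ratio cross 1. A trailing plateau suggests the
follow-up window already captures the full effect; these thresholds are
descriptive configuration, not inference.

## Trial simulator

Subjects enter uniformly over an accrual window (default 12 time units),
latent event times are drawn from the arm's mixture by inversion, and
censoring is the earlier of the administrative cutoff (study duration,
default 36, minus entry) and an exponential dropout draw (default hazard
0.01). Observed time is study time from entry. Four presets encode the
canonical non-PH shapes (constants documented in `scenarios.py`):
proportional hazards (Exp(10) vs Exp(14)), delayed separation (Exp(8) vs
0.5·W(8,1) + 0.5·W(20,0.5), chosen so the true Δ(3) is below 0.05 in
magnitude··· ≈ −0.09, while Δ(30) ≈ 3), crossing (Exp(10) vs
0.3·W(2,0.5) + 0.7·W(18,3), survival curves crossing near t ≈ 2–3), and
cure (Exp(10) vs 0.75·W(8,1) + 0.25·W(10⁴,1), treatment survival
plateauing near 0.25). `true_rmst_curve` returns the exact μ, Δ and θ of
the generating models, the truth oracle for recovery tests.

What the simulator does *not* emulate: covariate effects, non-uniform
accrual, informative censoring, ties from coarse visit schedules, and
model misspecification (the fitted family contains the truth). Passing
recovery and coverage checks therefore demonstrates the estimator and its
inference are correct *under the model*, not that three Weibull components
suffice for any given real trial — that remains a fit-quality judgement,
for which the KM agreement diagnostic is the intended tool.

## Validation studies and problem sizes

The replicate studies in `validation.py` (shared by the test suite and
`scripts/acceptance.py`) use the following designs:

* closed forms vs adaptive quadrature: 200 random mixtures (scales in
  [0.3, 30], shapes in [0.3, 4]) and horizons, agreement demanded to 1e−8;
* no-censoring KM identity: 100 random small datasets with forced ties;
* preset recovery: 2000 subjects/arm, fits at the preset's true component
  counts, sup-norm of the fitted vs true survival on [0, τ_d] averaged
  over replicates (10 in the test suite, 5 in the acceptance script) plus
  the rate at which μ̂(τ_d) lands within 3 delta-method se of the truth;
* coverage / type-I error: a well-separated two-component-per-arm
  scenario (control 0.6·W(5,1.5) + 0.4·W(18,2.5), treatment
  0.5·W(7,1.5) + 0.5·W(22,2.5), τ* = 12), 300 subjects/arm, 500
  replicates in the test suite (300 in the acceptance script, a runtime
  choice); replicates with a singular information matrix count as
  non-covering;
* KM agreement: 5000 subjects/arm from the two-component truth, maximum
  |mixture − KM| RMST over a shared grid measured in KM se units.

Fits inside the replicate loops use 2–4 multi-starts rather than the
default 10: the scenarios are well identified and the quantile-split start
is reliable there, and the studies remain deterministic given their seeds.

## Known limitations

* No covariate adjustment and no regression mixtures; arms are fitted
  independently.
* Pointwise intervals only — no simultaneous (uniform-in-τ) bands, so the
  curve's CI ribbon cannot be read as a joint statement over τ.
* Delta-method inference is first-order; at small n or near-boundary
  weights the normal approximation can be rough, and the information-based
  covariance can be ill-conditioned (warned).
* Mixture likelihoods are multimodal; multi-start mitigates but does not
  prove global optimality.
* Extrapolation beyond follow-up inherits the parametric assumption
  entirely; the 1.5 × τ_d cap is a guardrail, not a guarantee.
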