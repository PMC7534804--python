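# dynrmst

Dynamic restricted mean survival time (RMST) curves for two-arm survival
trials, built on a parametric mixture-of-Weibulls survival model.

## Why

In immuno-oncology and similar trials the proportional-hazards assumption
routinely fails — delayed treatment effects, crossing hazards, cure
fractions — so a single hazard ratio is a poor summary and the log-rank
test loses power. The RMST

μ(τ) = E[min(T, τ)] = ∫₀^τ S(t) dt

is the τ-window life expectancy: model-free, clinically interpretable, and
valid whatever the hazard shapes. Rather than reporting it at one horizon,
`dynrmst` traces the **dynamic RMST curve**: the between-arm difference
Δ(τ) = μ₁(τ) − μ₀(τ) and ratio θ(τ) = μ₁(τ)/μ₀(τ), with pointwise
confidence intervals, over a whole range of restriction times τ — an
evolving treatment-effect profile. The KM-based version of this curve
stops at the end of follow-up and gets noisy in the tail; the parametric
version stays smooth and can extrapolate moderately beyond follow-up.

## The model

Each arm's survival function is a mixture of up to three Weibull
components,

S(t) = Σⱼ pⱼ exp[−(t/λⱼ)^kⱼ],  λⱼ, kⱼ > 0,  Σ pⱼ = 1,

fitted by right-censored maximum likelihood (multi-start quasi-Newton on
log-scales, log-shapes and weight logits). The RMST of a fitted mixture is
closed-form in the lower incomplete gamma function γ(s, x):

∫₀^τ exp[−(t/λ)^k] dt = (λ/k) γ(1/k, (τ/λ)^k),

so μ(τ), the restricted variance 2∫₀^τ tS dt − μ², Δ(τ), θ(τ) and the
restricted-mean-time-lost (RMTL) ratio (τ−μ₁)/(τ−μ₀) are all evaluated
exactly at any τ. Standard errors come from the delta method on the
observed-information covariance; ratio CIs are formed on the log scale.
Every curve is cross-checked against the nonparametric KM-based RMST with
its classical variance.

## Worked example

```python
import dynrmst as dr

sc = dr.preset("delayed", n_per_arm=2000, seed=3)   # delayed-effect trial
ds = dr.simulate_trial(sc)
m0 = dr.fit_mixture(ds.control,   n_components=1, seed=1)
m1 = dr.fit_mixture(ds.treatment, n_components=2, seed=2)

tau = ds.default_tau()            # min over arms of the largest observed time
print(round(tau, 3))              # 34.983
d = dr.rmst_contrast(m0, m1, tau, "difference")
r = dr.rmst_contrast(m0, m1, tau, "ratio")
print(round(d.estimate, 3), round(d.se, 3), round(d.p_value, 6))
# 3.258 0.329 0.0
print(round(r.estimate, 3), (round(r.ci_low, 3), round(r.ci_high, 3)))
# 1.404 (1.316, 1.498)
```

The treatment adds about 3.3 time units of life expectancy within the
~35-unit window (a 40% relative gain), and the interval excludes no
effect. The full profile — and its agreement with the KM version — comes
from `build_dynamic_curve`:

```python
curve = dr.build_dynamic_curve(ds, m0, m1)          # 100-point tau grid
print(dr.km_mixture_agreement(curve)["treatment"]["max_in_km_se"])
# 0.6992384288216232  (worst mixture-vs-KM gap, in KM se units)
print(dr.follow_up_adequacy(curve).ratio_plateau)   # has theta(tau) stabilized?
# False  (the ratio is still climbing at the end of follow-up)
curve.plot("curve.png")                             # Delta and theta panels
```

The same pipeline is available from the shell:

```
dynrmst simulate --preset delayed --n-per-arm 2000 --seed 3 --output trial.csv
dynrmst fit   --input trial.csv --control-label control --n-components 2 --output-prefix model
dynrmst curve --input trial.csv --control-label control --model-prefix model --output curve.csv
dynrmst km    --input trial.csv --control-label control --output km.csv
```

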