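"""Simulation studies validating the estimators end to end.

These routines are the package's own quality checks: closed-form restricted
moments against adaptive quadrature, the no-censoring KM-RMST identity,
parameter/function recovery on the scenario presets, confidence-interval
coverage and type-I error, and mixture-vs-KM agreement.  They are used by
the test suite and by ``scripts/acceptance.py``; all are deterministic
given their seeds.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import integrate

from .data import ArmData
from .km import km_fit, km_rmst
from .mixture import MixtureWeibullModel, WeibullComponent, fit_mixture
from .rmst import (
    component_restricted_moment,
    mixture_rmst,
    rmst_contrast,
    rmst_with_ci,
)
from .scenarios import PRESET_COMPONENTS, TrialScenario, preset, simulate_trial

__all__ = [
    "closed_form_vs_quadrature",
    "km_no_censoring_identity",
    "random_mixture",
    "preset_recovery",
    "coverage_study",
    "type_one_error_study",
    "agreement_study",
    "two_component_scenario",
]


def random_mixture(rng: np.random.Generator, max_components: int = 3) -> MixtureWeibullModel:
    """A random valid mixture: scales in [0.3, 30], shapes in [0.3, 4]."""
    J = int(rng.integers(1, max_components + 1))
    lam = rng.uniform(0.3, 30.0, size=J)
    k = rng.uniform(0.3, 4.0, size=J)
    w = rng.dirichlet(np.ones(J))
    w = np.clip(w, 0.01, None)
    w /= w.sum()
    return MixtureWeibullModel(
        components=tuple(WeibullComponent(L, K) for L, K in zip(lam, k)),
        weights=tuple(w),
    )


def closed_form_vs_quadrature(seed: int, n_sets: int = 200) -> dict:
    """Max |closed form - adaptive quadrature| over random (lam, k, p, tau)
    configurations, for mu(tau) and the restricted second-moment integral
    int_0^tau t S(t) dt."""
    rng = np.random.default_rng(seed)
    worst_mu = 0.0
    worst_second = 0.0
    for _ in range(n_sets):
        model = random_mixture(rng)
        tau = float(rng.uniform(0.1, 50.0))
        mu = mixture_rmst(model, tau)
        mu_quad, _ = integrate.quad(
            lambda t: model.survival(t), 0.0, tau, limit=200, epsabs=1e-12, epsrel=1e-12
        )
        second = sum(
            w * component_restricted_moment(c.lam, c.k, tau, order=1)
            for w, c in zip(model.weights, model.components)
        )
        second_quad, _ = integrate.quad(
            lambda t: t * model.survival(t), 0.0, tau, limit=200, epsabs=1e-12, epsrel=1e-12
        )
        worst_mu = max(worst_mu, abs(mu - mu_quad))
        worst_second = max(worst_second, abs(second - second_quad))
    return {"max_abs_err_mu": worst_mu, "max_abs_err_second_moment": worst_second, "n_sets": n_sets}


def km_no_censoring_identity(seed: int, n_datasets: int = 100) -> dict:
    """Max |KM RMST - mean(min(t_i, tau))| over random fully-observed samples.

    With no censoring the area under the KM step function equals the plug-in
    sample mean of the truncated times exactly.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_datasets):
        n = int(rng.integers(3, 40))
        t = rng.gamma(2.0, 2.0, size=n).round(int(rng.integers(0, 3)))  # force some ties
        t = np.clip(t, 0.01, None)
        arm = ArmData("a", t, np.ones(n, dtype=int))
        tau = float(rng.uniform(0.5, 1.0) * t.max())
        est = km_rmst(km_fit(arm), tau).estimate
        worst = max(worst, abs(est - float(np.mean(np.minimum(t, tau)))))
    return {"max_abs_err": worst, "n_datasets": n_datasets}


def _fit_trial(ds, preset_name, seed, n_starts=4):
    j0, j1 = PRESET_COMPONENTS[preset_name]
    m0 = fit_mixture(ds.control, n_components=j0, n_starts=n_starts, seed=seed)
    m1 = fit_mixture(ds.treatment, n_components=j1, n_starts=n_starts, seed=seed + 1)
    return m0, m1


def preset_recovery(
    preset_name: str,
    seed: int,
    n_per_arm: int = 2000,
    n_replicates: int = 10,
    n_starts: int = 4,
) -> dict:
    """Simulate, fit with the preset's correct component counts, and compare
    to the generating truth.

    Reports the replicate-averaged sup-norm error of the fitted survival
    curves on [0, default tau] and the fraction of replicates whose
    mixture RMST at the default tau falls within 3 delta-method standard
    errors of the truth (both arms required).
    """
    sup_norms = []
    hits = 0
    usable = 0
    base = np.random.default_rng([seed, hash(preset_name) % (2**31)]).integers(2**31 - 1)
    for rep in range(n_replicates):
        sc = preset(preset_name, n_per_arm=n_per_arm, seed=int(base) + 1000 * rep)
        ds = simulate_trial(sc)
        tau_d = ds.default_tau()
        grid = np.linspace(tau_d / 200.0, tau_d, 200)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m0, m1 = _fit_trial(ds, preset_name, seed=int(base) + 7 * rep, n_starts=n_starts)
            sup = max(
                float(np.max(np.abs(np.asarray(m0.survival(grid)) - np.asarray(sc.model0.survival(grid))))),
                float(np.max(np.abs(np.asarray(m1.survival(grid)) - np.asarray(sc.model1.survival(grid))))),
            )
            sup_norms.append(sup)
            if m0.has_covariance and m1.has_covariance:
                usable += 1
                ok = True
                for model, truth in ((m0, sc.model0), (m1, sc.model1)):
                    est = rmst_with_ci(model, tau_d)
                    true_mu = mixture_rmst(truth, tau_d)
                    if est.se == 0 or abs(est.estimate - true_mu) > 3.0 * est.se:
                        ok = False
                hits += ok
    return {
        "mean_sup_norm": float(np.mean(sup_norms)),
        "max_sup_norm": float(np.max(sup_norms)),
        "within_3se_rate": hits / max(usable, 1),
        "n_usable": usable,
        "n_replicates": n_replicates,
        "n_per_arm": n_per_arm,
    }


def two_component_scenario(seed: int = 0, n_per_arm: int = 300) -> TrialScenario:
    """A well-identified two-component-per-arm scenario for coverage studies:
    both arms mix an early component with a clearly separated late one."""
    model0 = MixtureWeibullModel(
        components=(WeibullComponent(5.0, 1.5), WeibullComponent(18.0, 2.5)),
        weights=(0.6, 0.4),
    )
    model1 = MixtureWeibullModel(
        components=(WeibullComponent(7.0, 1.5), WeibullComponent(22.0, 2.5)),
        weights=(0.5, 0.5),
    )
    return TrialScenario(
        name="two_component",
        model0=model0,
        model1=model1,
        accrual=12.0,
        duration=36.0,
        dropout_rate=0.01,
        n_per_arm=n_per_arm,
        seed=seed,
    )


def coverage_study(
    seed: int,
    n_replicates: int = 500,
    n_per_arm: int = 300,
    tau_star: float = 12.0,
    n_starts: int = 2,
) -> dict:
    """Empirical coverage of the 95% CI for Delta(tau*) under the
    two-component scenario.  Replicates whose observed information is
    singular in either arm are counted as non-covering (they produce no
    interval)."""
    sc0 = two_component_scenario()
    true_delta = mixture_rmst(sc0.model1, tau_star) - mixture_rmst(sc0.model0, tau_star)
    rng = np.random.default_rng(seed)
    covered = 0
    total = 0
    for _ in range(n_replicates):
        sc = replace(sc0, n_per_arm=n_per_arm, seed=int(rng.integers(2**31 - 1)))
        ds = simulate_trial(sc)
        total += 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                m0 = fit_mixture(ds.control, n_components=2, n_starts=n_starts, seed=sc.seed)
                m1 = fit_mixture(ds.treatment, n_components=2, n_starts=n_starts, seed=sc.seed + 1)
                c = rmst_contrast(m0, m1, tau_star, "difference")
            except Exception:
                continue
        if c.ci_low <= true_delta <= c.ci_high:
            covered += 1
    return {
        "coverage": covered / total,
        "true_delta": float(true_delta),
        "n_replicates": total,
        "tau_star": tau_star,
    }


def type_one_error_study(
    seed: int,
    n_replicates: int = 500,
    n_per_arm: int = 300,
    tau_star: float = 12.0,
    alpha: float = 0.05,
    n_starts: int = 2,
) -> dict:
    """Two-sided rejection rate of H0: Delta(tau*) = 0 when both arms are
    drawn from the same two-component mixture."""
    sc0 = two_component_scenario()
    null = replace(sc0, model1=sc0.model0)
    rng = np.random.default_rng(seed)
    rejected = 0
    total = 0
    for _ in range(n_replicates):
        sc = replace(null, n_per_arm=n_per_arm, seed=int(rng.integers(2**31 - 1)))
        ds = simulate_trial(sc)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                m0 = fit_mixture(ds.control, n_components=2, n_starts=n_starts, seed=sc.seed)
                m1 = fit_mixture(ds.treatment, n_components=2, n_starts=n_starts, seed=sc.seed + 1)
                c = rmst_contrast(m0, m1, tau_star, "difference", alpha=alpha)
            except Exception:
                continue
        total += 1
        rejected += c.p_value < alpha
    return {
        "rejection_rate": rejected / max(total, 1),
        "n_replicates": total,
        "alpha": alpha,
        "tau_star": tau_star,
    }


def agreement_study(seed: int, n_per_arm: int = 5000, n_grid: int = 25) -> dict:
    """Simulate a large mixture-truth trial, fit, and measure the maximum
    |mixture - KM| RMST discrepancy in units of the KM standard error over
    a shared grid (both arms)."""
    from .curves import build_dynamic_curve, km_mixture_agreement

    sc = two_component_scenario(seed=seed, n_per_arm=n_per_arm)
    ds = simulate_trial(sc)
    tau_d = ds.default_tau()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m0 = fit_mixture(ds.control, n_components=2, n_starts=3, seed=seed)
        m1 = fit_mixture(ds.treatment, n_components=2, n_starts=3, seed=seed + 1)
        curve = build_dynamic_curve(
            ds, m0, m1, grid=np.linspace(tau_d / n_grid, tau_d, n_grid)
        )
    summary = km_mixture_agreement(curve)
    return {
        "max_in_km_se": max(summary["control"]["max_in_km_se"], summary["treatment"]["max_in_km_se"]),
        "max_abs": max(summary["control"]["max_abs"], summary["treatment"]["max_abs"]),
        "n_per_arm": n_per_arm,
        "per_arm": summary,
    }
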