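"""Kaplan-Meier product-limit estimation and KM-based RMST.

This is the nonparametric reference the parametric dynamic curves are
checked against.  The product-limit fit itself is delegated to
``lifelines.KaplanMeierFitter``; this module adds the step-function RMST
(exact area under the KM curve up to a horizon tau) and its classical
variance

    var[mu_hat(tau)] = sum_i A_i^2 * d_i / (n_i * (n_i - d_i)),

where the sum runs over distinct event times t_(i) <= tau, d_i and n_i are
the event and at-risk counts, and A_i is the area under the KM curve from
t_(i) to tau.  Terms with n_i = d_i (the curve hits zero) are dropped with
a warning.  Deaths precede censorings at tied times, the standard
product-limit convention.  The KM curve -- and hence the KM RMST -- is not
defined beyond the largest observed time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .data import ArmData
from .exceptions import EstimationError
from .rmst import ContrastEstimate, RmstEstimate, _safe_z, _two_sided_p

__all__ = ["StepSurvivalCurve", "km_fit", "km_rmst", "km_rmst_contrast"]


@dataclass(frozen=True)
class StepSurvivalCurve:
    """Product-limit estimate for one arm.

    ``times`` holds the distinct event times only; ``survival`` the KM
    estimate just after each, ``greenwood`` the cumulative sums of
    d/(n(n-d)) used by Greenwood's variance formula.  ``max_time`` is the
    largest observed time (event or censored), the end of the curve's
    support.
    """

    label: str
    times: np.ndarray  # distinct event times, increasing
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray  # S-hat at each event time (right-continuous step)
    greenwood: np.ndarray  # cumulative sum of d/(n(n-d)); 0 contribution when n==d
    max_time: float

    def survival_at(self, t):
        """Step-function evaluation of S-hat (right-continuous)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return s if s.ndim else float(s)

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: time, n_risk, n_event, survival, std_err (Greenwood)."""
        with np.errstate(invalid="ignore"):
            std_err = self.survival * np.sqrt(self.greenwood)
        return pd.DataFrame(
            {
                "time": self.times,
                "n_risk": self.n_risk,
                "n_event": self.n_event,
                "survival": self.survival,
                "std_err": std_err,
            }
        )


def km_fit(arm: ArmData) -> StepSurvivalCurve:
    """Product-limit estimate S-hat(t) = prod_{t_(i)<=t} (1 - d_i/n_i)."""
    if arm.n_events < 1:
        raise EstimationError(f"arm {arm.label!r} has no events; KM fit undefined")
    kmf = KaplanMeierFitter()
    kmf.fit(arm.time, event_observed=arm.event, label=arm.label)
    table = kmf.event_table
    mask = table["observed"] > 0
    times = table.index.to_numpy(dtype=float)[mask.to_numpy()]
    d = table.loc[mask, "observed"].to_numpy(dtype=float)
    n = table.loc[mask, "at_risk"].to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    return StepSurvivalCurve(
        label=arm.label,
        times=times,
        n_risk=n,
        n_event=d,
        survival=surv,
        greenwood=np.cumsum(terms),
        max_time=arm.max_time,
    )


def _area_to_tau(curve: StepSurvivalCurve, tau: float) -> tuple[float, np.ndarray]:
    """Exact area under the step function on [0, tau] and the per-event-time
    tail areas A_i (area from t_(i) to tau), for event times <= tau."""
    t = curve.times
    s = curve.survival
    within = t <= tau
    tw = t[within]
    sw = s[within]
    knots = np.concatenate([[0.0], tw, [tau]])
    heights = np.concatenate([[1.0], sw])  # value on each interval
    widths = np.diff(knots)
    segment_areas = heights * widths
    total = float(segment_areas.sum())
    # tail area from each event time t_(i): sum of segments starting at t_(i)
    rev = np.cumsum(segment_areas[::-1])[::-1]  # rev[j] = area from knots[j-? ]
    # segment j covers [knots[j], knots[j+1]); segment index for event i is i+1
    tails = rev[1:] if tw.size else np.empty(0)
    return total, tails


def km_rmst(curve: StepSurvivalCurve, tau: float, alpha: float = 0.05) -> RmstEstimate:
    """KM-based RMST at ``tau``: area under the step curve with the classical
    variance; normal CI.  ``tau`` must lie within the curve's support."""
    tau = float(tau)
    if not (0 < tau <= curve.max_time):
        raise EstimationError(
            f"tau={tau} outside the KM support (0, {curve.max_time}]; "
            "use the parametric mixture engine to extrapolate beyond follow-up"
        )
    area, tails = _area_to_tau(curve, tau)
    within = curve.times <= tau
    d = curve.n_event[within]
    n = curve.n_risk[within]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(n > d, d / (n * (n - d)), np.nan)
    if np.any(np.isnan(w)):
        warnings.warn(
            "last at-risk subject had an event; its variance term is dropped",
            RuntimeWarning,
            stacklevel=2,
        )
        w = np.nan_to_num(w, nan=0.0)
    var = float(np.sum(tails**2 * w))
    se = float(np.sqrt(var))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return RmstEstimate(
        tau=tau,
        estimate=area,
        se=se,
        ci_low=area - z * se,
        ci_high=area + z * se,
        alpha=alpha,
    )


def km_rmst_contrast(
    curve0: StepSurvivalCurve,
    curve1: StepSurvivalCurve,
    tau: float,
    alpha: float = 0.05,
) -> tuple[ContrastEstimate, ContrastEstimate]:
    """KM-based RMST difference and ratio (arm 1 vs arm 0) at ``tau``.

    Independent arms: var(Delta) = var1 + var0.  The ratio CI is computed
    on the log scale and exponentiated.  Returns (difference, ratio).
    """
    tau = float(tau)
    r0 = km_rmst(curve0, tau, alpha=alpha)
    r1 = km_rmst(curve1, tau, alpha=alpha)
    z = stats.norm.ppf(1.0 - alpha / 2.0)

    diff = r1.estimate - r0.estimate
    se_d = float(np.hypot(r0.se, r1.se))
    difference = ContrastEstimate(
        tau=tau,
        kind="difference",
        estimate=diff,
        se=se_d,
        ci_low=diff - z * se_d,
        ci_high=diff + z * se_d,
        p_value=_two_sided_p(_safe_z(diff, se_d)),
        alpha=alpha,
    )

    if r0.estimate <= 0 or r1.estimate <= 0:
        raise EstimationError("RMST ratio requires positive restricted means")
    est = r1.estimate / r0.estimate
    log_se = float(
        np.sqrt((r1.se / r1.estimate) ** 2 + (r0.se / r0.estimate) ** 2)
    )
    log_est = float(np.log(est))
    ratio = ContrastEstimate(
        tau=tau,
        kind="ratio",
        estimate=est,
        se=log_se,
        ci_low=float(np.exp(log_est - z * log_se)),
        ci_high=float(np.exp(log_est + z * log_se)),
        p_value=_two_sided_p(_safe_z(log_est, log_se)),
        alpha=alpha,
    )
    return difference, ratio
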