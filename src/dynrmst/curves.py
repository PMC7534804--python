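"""Dynamic RMST curves: the treatment-effect profile traced over horizons.

A :class:`DynamicCurve` evaluates, at every point of a tau grid, the
per-arm restricted means with pointwise confidence intervals and the
between-arm difference and ratio (optionally the RMTL ratio), from two
engines:

* the parametric mixture-Weibull engine, defined at any tau (extrapolation
  beyond the default horizon is allowed up to a configurable multiple,
  with a warning -- parametric extrapolation far past follow-up is
  unreliable);
* the nonparametric KM engine, defined only while the KM curves exist:
  per-arm estimates up to that arm's largest observed time, contrasts up
  to the smaller of the two.

The default horizon ("default tau") is the minimum over arms of each
arm's largest observed time -- the largest tau at which both KM-based
RMSTs exist.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .exceptions import ConfigError, DiagnosticError
from .km import StepSurvivalCurve, km_fit, km_rmst, km_rmst_contrast
from .mixture import MixtureWeibullModel
from .rmst import ContrastEstimate, RmstEstimate, rmst_contrast, rmst_with_ci

__all__ = [
    "DynamicCurve",
    "PlateauReport",
    "build_dynamic_curve",
    "km_mixture_agreement",
    "follow_up_adequacy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DynamicCurve:
    """Per-grid-point estimates and contrasts from both engines.

    KM entries are ``None`` (absent, not zero) at grid points beyond the
    relevant support.
    """

    grid: np.ndarray
    default_tau: float
    km_boundary: float  # largest tau with KM support in both arms
    arm_labels: tuple[str, str]  # (control, treatment)
    mixture_arm0: list[RmstEstimate]
    mixture_arm1: list[RmstEstimate]
    mixture_difference: list[ContrastEstimate]
    mixture_ratio: list[ContrastEstimate]
    mixture_rmtl_ratio: list[ContrastEstimate] | None
    km_arm0: list[RmstEstimate | None]
    km_arm1: list[RmstEstimate | None]
    km_difference: list[ContrastEstimate | None]
    km_ratio: list[ContrastEstimate | None]
    alpha: float = 0.05
    km_curves: tuple[StepSurvivalCurve, StepSurvivalCurve] | None = field(
        default=None, compare=False
    )

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: tau, series, engine, estimate, se, ci_low, ci_high,
        p_value (NaN where not applicable)."""
        rows = []

        def add(tau, series, engine, obj):
            if obj is None:
                return
            rows.append(
                {
                    "tau": tau,
                    "series": series,
                    "engine": engine,
                    "estimate": obj.estimate,
                    "se": obj.se,
                    "ci_low": obj.ci_low,
                    "ci_high": obj.ci_high,
                    "p_value": getattr(obj, "p_value", np.nan),
                }
            )

        c, t = self.arm_labels
        for i, tau in enumerate(self.grid):
            add(tau, f"rmst_{c}", "mixture", self.mixture_arm0[i])
            add(tau, f"rmst_{t}", "mixture", self.mixture_arm1[i])
            add(tau, "difference", "mixture", self.mixture_difference[i])
            add(tau, "ratio", "mixture", self.mixture_ratio[i])
            if self.mixture_rmtl_ratio is not None:
                add(tau, "rmtl_ratio", "mixture", self.mixture_rmtl_ratio[i])
            add(tau, f"rmst_{c}", "km", self.km_arm0[i])
            add(tau, f"rmst_{t}", "km", self.km_arm1[i])
            add(tau, "difference", "km", self.km_difference[i])
            add(tau, "ratio", "km", self.km_ratio[i])
        return pd.DataFrame(rows)

    def plot(self, path=None):
        """Two-panel figure: Delta(tau) and theta(tau) with CI ribbons from
        both engines; the default tau is marked.  Returns the Figure."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(11, 4.2), sharex=True)
        series = [("difference", self.mixture_difference, self.km_difference, 0.0),
                  ("ratio", self.mixture_ratio, self.km_ratio, 1.0)]
        for ax, (name, mix, km, ref) in zip(axes, series):
            est = [c.estimate for c in mix]
            lo = [c.ci_low for c in mix]
            hi = [c.ci_high for c in mix]
            ax.plot(self.grid, est, color="C0", label="mixture")
            ax.fill_between(self.grid, lo, hi, color="C0", alpha=0.2)
            kt = [tau for tau, c in zip(self.grid, km) if c is not None]
            if kt:
                ax.plot(kt, [c.estimate for c in km if c is not None], "C1--", label="KM")
                ax.fill_between(
                    kt,
                    [c.ci_low for c in km if c is not None],
                    [c.ci_high for c in km if c is not None],
                    color="C1",
                    alpha=0.15,
                )
            ax.axhline(ref, color="grey", lw=0.8)
            ax.axvline(self.default_tau, color="grey", lw=0.8, ls=":")
            ax.set_xlabel("restriction time tau")
            ax.set_ylabel(f"RMST {name}")
            ax.legend(frameon=False)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
        return fig


def _resolve_grid(grid_spec, default_tau: float, factor: float):
    if grid_spec is None:
        grid = np.linspace(default_tau / 100.0, default_tau, 100)
    elif isinstance(grid_spec, tuple) and len(grid_spec) == 3:
        lo, hi, n = grid_spec
        if lo <= 0 or hi < lo or int(n) < 1 or (hi == lo and int(n) > 1):
            raise ConfigError("grid spec must satisfy 0 < tau_min <= tau_max, n >= 1")
        grid = np.linspace(float(lo), float(hi), int(n))
    else:
        grid = np.asarray(grid_spec, dtype=float)
        if grid.ndim != 1 or grid.size == 0:
            raise ConfigError("explicit grid must be a nonempty 1-D array")
        if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
            raise ConfigError("grid must be strictly increasing and positive")
    cap = factor * default_tau
    if grid[-1] > cap * (1 + 1e-12):
        warnings.warn(
            f"grid extends to {grid[-1]:.4g}, beyond {factor} x default tau "
            f"({cap:.4g}); clamping to limit extrapolation",
            RuntimeWarning,
            stacklevel=3,
        )
        grid = grid[grid <= cap]
        if grid.size == 0:
            raise ConfigError("grid entirely beyond the extrapolation cap")
    return grid


def build_dynamic_curve(
    ds: SurvivalDataset,
    model0: MixtureWeibullModel,
    model1: MixtureWeibullModel,
    grid=None,
    alpha: float = 0.05,
    extrapolation_factor: float = 1.5,
    include_rmtl_ratio: bool = False,
) -> DynamicCurve:
    """Evaluate mixture- and KM-based RMST estimates and contrasts over a
    tau grid.

    ``grid`` may be None (100 points up to the default tau), a
    ``(tau_min, tau_max, n)`` tuple, or an explicit increasing array.
    Mixture results exist at every point; KM results only within support.
    """
    if not (0 < alpha < 1):
        raise ConfigError("alpha must be in (0, 1)")
    default_tau = ds.default_tau()
    grid = _resolve_grid(grid, default_tau, extrapolation_factor)
    if grid[-1] > default_tau:
        logger.warning(
            "grid extends beyond the default tau %.4g; parametric extrapolation in use",
            default_tau,
        )

    curve0 = km_fit(ds.control)
    curve1 = km_fit(ds.treatment)
    km_boundary = min(curve0.max_time, curve1.max_time)

    mix0, mix1, mdiff, mratio = [], [], [], []
    mrmtl = [] if include_rmtl_ratio else None
    k0, k1, kdiff, kratio = [], [], [], []
    for tau in grid:
        mix0.append(rmst_with_ci(model0, tau, alpha=alpha))
        mix1.append(rmst_with_ci(model1, tau, alpha=alpha))
        mdiff.append(rmst_contrast(model0, model1, tau, "difference", alpha=alpha))
        mratio.append(rmst_contrast(model0, model1, tau, "ratio", alpha=alpha))
        if mrmtl is not None:
            mrmtl.append(rmst_contrast(model0, model1, tau, "rmtl_ratio", alpha=alpha))
        k0.append(km_rmst(curve0, tau, alpha=alpha) if tau <= curve0.max_time else None)
        k1.append(km_rmst(curve1, tau, alpha=alpha) if tau <= curve1.max_time else None)
        if tau <= km_boundary:
            d, r = km_rmst_contrast(curve0, curve1, tau, alpha=alpha)
        else:
            d = r = None
        kdiff.append(d)
        kratio.append(r)

    return DynamicCurve(
        grid=grid,
        default_tau=default_tau,
        km_boundary=km_boundary,
        arm_labels=ds.labels,
        mixture_arm0=mix0,
        mixture_arm1=mix1,
        mixture_difference=mdiff,
        mixture_ratio=mratio,
        mixture_rmtl_ratio=mrmtl,
        km_arm0=k0,
        km_arm1=k1,
        km_difference=kdiff,
        km_ratio=kratio,
        alpha=alpha,
        km_curves=(curve0, curve1),
    )


def km_mixture_agreement(curve: DynamicCurve) -> dict:
    """Summarize |mixture - KM| per-arm RMST discrepancies over the grid
    points where both engines are defined.

    Returns, per arm, the max and mean absolute discrepancy and the max
    discrepancy in units of the KM standard error.  Requires at least 3
    shared grid points.
    """
    out = {}
    for key, mix, km in (
        ("control", curve.mixture_arm0, curve.km_arm0),
        ("treatment", curve.mixture_arm1, curve.km_arm1),
    ):
        pairs = [(m.estimate, k.estimate, k.se) for m, k in zip(mix, km) if k is not None]
        if len(pairs) < 3:
            raise DiagnosticError(
                "fewer than 3 grid points with KM support; refine the grid"
            )
        diffs = np.array([abs(m - k) for m, k, _ in pairs])
        ses = np.array([se for _, _, se in pairs])
        with np.errstate(divide="ignore", invalid="ignore"):
            in_se = np.where(ses > 0, diffs / ses, np.inf * (diffs > 0))
        out[key] = {
            "max_abs": float(diffs.max()),
            "mean_abs": float(diffs.mean()),
            "max_in_km_se": float(np.max(in_se)),
            "n_shared": len(pairs),
        }
    return out


@dataclass(frozen=True)
class PlateauReport:
    """Descriptive trailing-window summary of the contrast curves."""

    window_fraction: float
    threshold: float
    difference_relative_change: float
    difference_plateau: bool
    ratio_relative_change: float
    ratio_plateau: bool
    crossing_tau: float | None  # grid point nearest where Delta changes sign


def _relative_change(values: np.ndarray) -> float:
    span = float(values.max() - values.min())
    scale = max(float(np.median(np.abs(values))), 1e-12)
    return span / scale


def follow_up_adequacy(
    curve: DynamicCurve, window: float = 0.2, threshold: float = 0.01
) -> PlateauReport:
    """Report whether the trailing ends of the Delta(tau) and theta(tau)
    curves have stabilized (a plateau suggests follow-up was long enough).

    Purely descriptive: the relative change of each contrast over the
    trailing ``window`` fraction of the grid is compared to ``threshold``.
    Also reports the grid point nearest any sign change of Delta (where
    theta crosses 1).
    """
    if curve.grid.size < 10:
        raise DiagnosticError("need at least 10 grid points for a plateau report")
    if not (0 < window < 1):
        raise ConfigError("window must be a fraction in (0, 1)")
    m = max(int(np.ceil(window * curve.grid.size)), 2)
    diff = np.array([c.estimate for c in curve.mixture_difference])
    ratio = np.array([c.estimate for c in curve.mixture_ratio])
    rc_diff = _relative_change(diff[-m:])
    rc_ratio = _relative_change(ratio[-m:])

    crossing = None
    signs = np.sign(diff)
    change = np.nonzero(np.diff(signs) != 0)[0]
    if change.size:
        i = change[0]
        # pick the grid point whose Delta is nearest zero around the change
        crossing = float(
            curve.grid[i] if abs(diff[i]) <= abs(diff[i + 1]) else curve.grid[i + 1]
        )
    return PlateauReport(
        window_fraction=window,
        threshold=threshold,
        difference_relative_change=rc_diff,
        difference_plateau=rc_diff < threshold,
        ratio_relative_change=rc_ratio,
        ratio_plateau=rc_ratio < threshold,
        crossing_tau=crossing,
    )
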