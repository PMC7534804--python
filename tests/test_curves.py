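import numpy as np
import pytest

import dynrmst as dr
from dynrmst.exceptions import ConfigError, DiagnosticError


@pytest.fixture(scope="module")
def ph_curve(request):
    sc = dr.preset("ph", n_per_arm=400, seed=11)
    ds = dr.simulate_trial(sc)
    m0 = dr.fit_mixture(ds.control, n_components=1, n_starts=3, seed=5)
    m1 = dr.fit_mixture(ds.treatment, n_components=1, n_starts=3, seed=6)
    curve = dr.build_dynamic_curve(ds, m0, m1, include_rmtl_ratio=True)
    return sc, ds, m0, m1, curve


class TestBuildDynamicCurve:
    def test_default_grid_ends_at_default_tau(self, ph_curve):
        _, ds, _, _, curve = ph_curve
        assert curve.grid.size == 100
        assert curve.grid[-1] == pytest.approx(ds.default_tau())
        assert np.all(np.diff(curve.grid) > 0)

    def test_single_point_grid_matches_single_tau_api(self, ph_curve):
        _, ds, m0, m1, _ = ph_curve
        tau = ds.default_tau()
        curve = dr.build_dynamic_curve(ds, m0, m1, grid=np.array([tau]))
        direct = dr.rmst_contrast(m0, m1, tau, "difference")
        assert curve.mixture_difference[0].estimate == direct.estimate
        assert curve.mixture_difference[0].se == direct.se
        direct_mu = dr.rmst_with_ci(m0, tau)
        assert curve.mixture_arm0[0].estimate == direct_mu.estimate

    def test_identical_arm_dataset_null_curves(self):
        rng = np.random.default_rng(4)
        t = rng.exponential(8, 150)
        e = (t < 20).astype(int)
        t = np.minimum(t, 20)
        ds = dr.SurvivalDataset(
            time=np.concatenate([t, t]),
            event=np.concatenate([e, e]),
            arm=["c"] * 150 + ["t"] * 150,
            control_label="c",
        )
        m = dr.fit_mixture(ds.control, n_components=1, n_starts=2, seed=0)
        curve = dr.build_dynamic_curve(ds, m, m)
        for c in curve.mixture_difference:
            assert c.estimate == pytest.approx(0.0, abs=1e-12)
        for c in curve.mixture_ratio:
            assert c.estimate == pytest.approx(1.0, abs=1e-12)
        for c in curve.km_difference:
            assert c is None or c.estimate == pytest.approx(0.0, abs=1e-12)

    def test_delayed_effect_sign_pattern(self, delayed_fit):
        sc, ds, m0, m1 = delayed_fit
        curve = dr.build_dynamic_curve(ds, m0, m1, grid=(1.0, 30.0, 30))
        truth = dr.true_rmst_curve(sc, curve.grid)
        est = np.array([c.estimate for c in curve.mixture_difference])
        # early separation negligible, late separation large, matching truth
        assert abs(truth["difference"].iloc[2]) < 0.2
        assert truth["difference"].iloc[-1] > 1.0
        assert est[-1] > 1.0
        assert np.max(np.abs(est - truth["difference"].to_numpy())) < 1.0

    def test_km_absent_beyond_boundary(self, ph_curve):
        _, ds, m0, m1, _ = ph_curve
        tau_d = ds.default_tau()
        curve = dr.build_dynamic_curve(ds, m0, m1, grid=(tau_d / 2, 1.4 * tau_d, 20))
        for tau, kd in zip(curve.grid, curve.km_difference):
            if tau > curve.km_boundary:
                assert kd is None
            else:
                assert kd is not None
        lo, hi = ds.max_observed_time(per_arm=True)
        for tau, k0 in zip(curve.grid, curve.km_arm0):
            assert (k0 is None) == (tau > lo)

    def test_extrapolation_clamped_with_warning(self, ph_curve):
        _, ds, m0, m1, _ = ph_curve
        tau_d = ds.default_tau()
        with pytest.warns(RuntimeWarning, match="clamping"):
            curve = dr.build_dynamic_curve(ds, m0, m1, grid=(1.0, 5 * tau_d, 50))
        assert curve.grid[-1] <= 1.5 * tau_d * (1 + 1e-9)

    def test_grid_refinement_pointwise_stable(self, ph_curve):
        _, ds, m0, m1, _ = ph_curve
        coarse = dr.build_dynamic_curve(ds, m0, m1, grid=np.array([4.0, 8.0]))
        fine = dr.build_dynamic_curve(ds, m0, m1, grid=np.array([2.0, 4.0, 6.0, 8.0]))
        assert coarse.mixture_difference[0].estimate == fine.mixture_difference[1].estimate
        assert coarse.km_ratio[1].estimate == fine.km_ratio[3].estimate

    def test_mu_at_most_tau_everywhere(self, ph_curve):
        _, _, _, _, curve = ph_curve
        for tau, a0, a1 in zip(curve.grid, curve.mixture_arm0, curve.mixture_arm1):
            assert a0.estimate <= tau + 1e-12
            assert a1.estimate <= tau + 1e-12

    def test_empty_or_bad_grid_rejected(self, ph_curve):
        _, ds, m0, m1, _ = ph_curve
        with pytest.raises(ConfigError):
            dr.build_dynamic_curve(ds, m0, m1, grid=np.array([]))
        with pytest.raises(ConfigError):
            dr.build_dynamic_curve(ds, m0, m1, grid=np.array([-1.0, 2.0]))

    def test_tidy_export_schema(self, ph_curve):
        _, _, _, _, curve = ph_curve
        frame = curve.to_frame()
        assert set(frame.columns) == {
            "tau", "series", "engine", "estimate", "se", "ci_low", "ci_high", "p_value",
        }
        assert set(frame["engine"]) == {"mixture", "km"}
        assert "rmtl_ratio" in set(frame["series"])

    def test_plot_writes_figure(self, ph_curve, tmp_path):
        _, _, _, _, curve = ph_curve
        out = tmp_path / "curve.png"
        fig = curve.plot(out)
        assert out.exists() and out.stat().st_size > 0
        import matplotlib.pyplot as plt

        plt.close(fig)


class TestAgreement:
    def test_large_sample_agreement_within_km_se(self):
        from dynrmst.validation import agreement_study

        result = agreement_study(seed=17, n_per_arm=3000, n_grid=12)
        assert result["max_in_km_se"] < 2.0

    def test_single_shared_point_is_error(self, ph_curve):
        _, ds, m0, m1, _ = ph_curve
        curve = dr.build_dynamic_curve(ds, m0, m1, grid=np.array([ds.default_tau()]))
        with pytest.raises(DiagnosticError):
            dr.km_mixture_agreement(curve)

    def test_identical_inputs_zero_discrepancy(self, ph_curve):
        # feed the mixture estimates as the KM estimates artificially
        from dataclasses import replace

        _, _, _, _, curve = ph_curve
        fake = replace(curve, km_arm0=list(curve.mixture_arm0), km_arm1=list(curve.mixture_arm1))
        summary = dr.km_mixture_agreement(fake)
        assert summary["control"]["max_abs"] == 0.0
        assert summary["treatment"]["max_abs"] == 0.0


class TestFollowUpAdequacy:
    def _synthetic_curve(self, diffs, ratios):
        from dataclasses import replace
        from dynrmst.rmst import ContrastEstimate

        grid = np.linspace(1, 20, len(diffs))
        mk = lambda kind, vals: [
            ContrastEstimate(tau=t, kind=kind, estimate=v, se=0.1, ci_low=v - 0.2,
                             ci_high=v + 0.2, p_value=0.5)
            for t, v in zip(grid, vals)
        ]
        return dr.DynamicCurve(
            grid=grid,
            default_tau=20.0,
            km_boundary=20.0,
            arm_labels=("c", "t"),
            mixture_arm0=[None] * len(diffs),
            mixture_arm1=[None] * len(diffs),
            mixture_difference=mk("difference", diffs),
            mixture_ratio=mk("ratio", ratios),
            mixture_rmtl_ratio=None,
            km_arm0=[None] * len(diffs),
            km_arm1=[None] * len(diffs),
            km_difference=[None] * len(diffs),
            km_ratio=[None] * len(diffs),
        )

    def test_constant_tail_flags_plateau(self):
        diffs = list(np.linspace(0.1, 2.0, 10)) + [2.0] * 10
        ratios = list(np.linspace(1.0, 1.5, 10)) + [1.5] * 10
        report = dr.follow_up_adequacy(self._synthetic_curve(diffs, ratios))
        assert report.difference_plateau and report.ratio_plateau
        assert report.difference_relative_change == pytest.approx(0.0)

    def test_growing_tail_not_plateau(self):
        diffs = list(np.linspace(0.1, 2.0, 15)) + list(np.linspace(2.0, 2.2, 5))
        ratios = list(np.linspace(1.0, 1.5, 15)) + list(np.linspace(1.5, 1.65, 5))
        report = dr.follow_up_adequacy(self._synthetic_curve(diffs, ratios))
        assert not report.difference_plateau
        assert not report.ratio_plateau

    def test_crossing_preset_reports_crossing_tau(self):
        sc = dr.preset("crossing", n_per_arm=2000, seed=21)
        truth = dr.true_rmst_curve(sc, np.linspace(0.25, 25, 100))
        d = truth["difference"].to_numpy()
        # truth crosses zero: worse early, better later
        assert d[1] < 0 and d[-1] > 0
        idx = np.nonzero(np.diff(np.sign(d)))[0][0]
        bracket = (truth["tau"].iloc[idx], truth["tau"].iloc[idx + 1])

        ds = dr.simulate_trial(sc)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m0 = dr.fit_mixture(ds.control, n_components=1, n_starts=3, seed=1)
            m1 = dr.fit_mixture(ds.treatment, n_components=2, n_starts=4, seed=2)
        curve = dr.build_dynamic_curve(ds, m0, m1, grid=(0.25, 25.0, 100))
        report = dr.follow_up_adequacy(curve)
        assert report.crossing_tau is not None
        # fitted crossing lands near the truth's bracket
        assert bracket[0] - 2.5 < report.crossing_tau < bracket[1] + 2.5

    def test_too_few_points_is_error(self, ph_curve):
        _, ds, m0, m1, _ = ph_curve
        small = dr.build_dynamic_curve(ds, m0, m1, grid=(1.0, 10.0, 5))
        with pytest.raises(DiagnosticError):
            dr.follow_up_adequacy(small)
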