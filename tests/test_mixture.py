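import numpy as np
import pytest
from scipy import integrate

import dynrmst as dr
from dynrmst.exceptions import FitError, LikelihoodError


def two_comp():
    return dr.MixtureWeibullModel(
        components=((1.0, 1.0), (2.0, 2.0)), weights=(0.5, 0.5)
    )


class TestEvaluation:
    def test_survival_at_zero_is_one(self):
        assert two_comp().survival(0.0) == pytest.approx(1.0)

    def test_single_exponential(self, exp_model):
        assert exp_model.survival(1.0) == pytest.approx(np.exp(-1), rel=1e-12)
        assert exp_model.density(0.7) == pytest.approx(np.exp(-0.7), rel=1e-12)
        np.testing.assert_allclose(exp_model.hazard([0.5, 1, 5]), 1.0, rtol=1e-12)

    def test_two_component_hand_sum(self):
        expected = 0.5 * np.exp(-1) + 0.5 * np.exp(-0.25)
        assert two_comp().survival(1.0) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            two_comp().survival(-0.1)

    def test_density_diverges_at_zero_for_small_shape(self):
        m = dr.MixtureWeibullModel(components=((1.0, 0.5),), weights=(1.0,))
        with pytest.raises(ValueError, match="diverges"):
            m.density(0.0)

    def test_density_integrates_to_one(self):
        m = dr.MixtureWeibullModel(
            components=((1.5, 0.8), (4.0, 2.5)), weights=(0.4, 0.6)
        )
        total, _ = integrate.quad(lambda t: m.density(t), 0, np.inf, limit=200)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_hazard_equals_minus_dlogS(self):
        m = two_comp()
        h = 1e-6
        for t in [0.3, 1.0, 2.7]:
            numeric = -(np.log(m.survival(t + h)) - np.log(m.survival(t - h))) / (2 * h)
            assert m.hazard(t) == pytest.approx(numeric, rel=1e-5)

    def test_survival_valid_on_dense_grid(self, rng):
        from dynrmst.validation import random_mixture

        for _ in range(10):
            m = random_mixture(rng)
            grid = np.linspace(0, 100, 400)
            s = np.asarray(m.survival(grid))
            assert s[0] == pytest.approx(1.0)
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((s >= 0) & (s <= 1))


class TestLogLikelihood:
    def test_exponential_event_term(self, exp_model):
        armd = dr.ArmData("x", [1.0], [1])
        assert dr.log_likelihood(exp_model, armd) == pytest.approx(-1.0, rel=1e-12)

    def test_exponential_censored_term(self, exp_model):
        armd = dr.ArmData("x", [2.0], [0])
        assert dr.log_likelihood(exp_model, armd) == pytest.approx(-2.0, rel=1e-12)

    def test_mixed_four_subject_sum(self):
        m = two_comp()
        t = np.array([0.5, 1.2, 2.0, 3.5])
        e = np.array([1, 0, 1, 0])
        expected = sum(
            np.log(m.density(ti)) if ei else np.log(m.survival(ti))
            for ti, ei in zip(t, e)
        )
        assert dr.log_likelihood(m, dr.ArmData("x", t, e)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_event_at_zero_is_likelihood_error(self):
        m = dr.MixtureWeibullModel(components=((1.0, 0.5),), weights=(1.0,))
        with pytest.raises(LikelihoodError):
            dr.log_likelihood(m, dr.ArmData("x", [0.0, 1.0], [1, 1]))

    def test_label_switching_invariance(self):
        m = dr.MixtureWeibullModel(
            components=((1.0, 1.0), (2.0, 2.0), (5.0, 0.7)), weights=(0.2, 0.3, 0.5)
        )
        perm = m.permuted([2, 0, 1])
        armd = dr.ArmData("x", [0.5, 1.5, 4.0], [1, 0, 1])
        t = np.linspace(0.01, 10, 50)
        np.testing.assert_allclose(m.survival(t), perm.survival(t), rtol=1e-12)
        np.testing.assert_allclose(m.density(t), perm.density(t), rtol=1e-12)
        assert dr.log_likelihood(m, armd) == pytest.approx(
            dr.log_likelihood(perm, armd), rel=1e-12
        )


class TestFit:
    def test_single_component_recovery(self):
        truth = dr.MixtureWeibullModel(components=((2.0, 1.5),), weights=(1.0,))
        t = dr.simulate_mixture(truth, 2000, seed=42)
        armd = dr.ArmData("x", t, np.ones(t.size, int))
        m = dr.fit_mixture(armd, n_components=1, n_starts=3, seed=0)
        assert m.components[0].lam == pytest.approx(2.0, rel=0.05)
        assert m.components[0].k == pytest.approx(1.5, rel=0.05)
        assert m.has_covariance

    def test_censored_exponential_matches_closed_form_mle(self, rng):
        # exponential MLE with censoring: lambda-hat = sum(t) / sum(delta)
        t_lat = rng.exponential(3.0, size=800)
        cens = rng.uniform(0, 6, size=800)
        t = np.minimum(t_lat, cens)
        e = (t_lat <= cens).astype(int)
        armd = dr.ArmData("x", t, e)
        m = dr.fit_mixture(armd, n_components=1, n_starts=3, seed=1)
        lam_hat = t.sum() / e.sum()
        assert m.components[0].k == pytest.approx(1.0, rel=0.08)
        assert m.components[0].lam == pytest.approx(lam_hat, rel=0.08)

    def test_no_events_is_fit_error(self):
        with pytest.raises(FitError, match="no events"):
            dr.fit_mixture(dr.ArmData("x", [1.0] * 20, [0] * 20), n_components=1)

    def test_row_permutation_gives_identical_optimum(self, rng):
        truth = two_comp()
        t = dr.simulate_mixture(truth, 300, seed=9)
        e = np.ones(t.size, int)
        armd = dr.ArmData("x", t, e)
        perm = rng.permutation(t.size)
        armp = dr.ArmData("x", t[perm], e[perm])
        m1 = dr.fit_mixture(armd, n_components=2, n_starts=2, seed=4)
        m2 = dr.fit_mixture(armp, n_components=2, n_starts=2, seed=4)
        assert m1.log_lik == m2.log_lik
        np.testing.assert_array_equal(m1.to_transformed(), m2.to_transformed())

    def test_optimum_beats_every_start(self, delayed_fit):
        _, _, m0, m1 = delayed_fit
        for m in (m0, m1):
            assert m.log_lik >= max(m.meta["start_log_liks"]) - 1e-9


class TestSelectComponents:
    def test_single_weibull_selects_one(self):
        truth = dr.MixtureWeibullModel(components=((3.0, 1.4),), weights=(1.0,))
        t = dr.simulate_mixture(truth, 1200, seed=7)
        armd = dr.ArmData("x", t, np.ones(t.size, int))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best, table = dr.select_components(armd, candidates=(1, 2), seed=0, n_starts=3)
        assert best.n_components == 1
        assert set(table["n_components"]) == {1, 2}

    def test_separated_mixture_selects_two(self):
        truth = dr.MixtureWeibullModel(
            components=((1.0, 1.0), (20.0, 1.0)), weights=(0.5, 0.5)
        )
        t = dr.simulate_mixture(truth, 1500, seed=8)
        armd = dr.ArmData("x", t, np.ones(t.size, int))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best, _ = dr.select_components(armd, candidates=(1, 2), seed=0, n_starts=3)
        assert best.n_components == 2

    def test_single_candidate_returns_that_fit(self):
        t = dr.simulate_mixture(two_comp(), 200, seed=3)
        armd = dr.ArmData("x", t, np.ones(t.size, int))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            best, table = dr.select_components(armd, candidates=(2,), seed=0, n_starts=2)
        assert best.n_components == 2
        assert len(table) == 1


class TestSimulate:
    def test_lln_mean(self, exp_model):
        t = dr.simulate_mixture(exp_model, 100_000, seed=1)
        # exponential mean 1, sd 1
        assert abs(t.mean() - 1.0) < 3.0 / np.sqrt(t.size)

    def test_dkw_band(self):
        m = two_comp()
        n = 10_000
        t = dr.simulate_mixture(m, n, seed=2)
        grid = np.linspace(0.1, 6, 30)
        emp = 1.0 - np.searchsorted(np.sort(t), grid, side="right") / n
        band = np.sqrt(np.log(2 / 0.001) / (2 * n))  # DKW at 99.9%
        assert np.max(np.abs(emp - np.asarray(m.survival(grid)))) < band

    def test_seed_reproducibility(self, exp_model):
        a = dr.simulate_mixture(exp_model, 1, seed=5)
        b = dr.simulate_mixture(exp_model, 1, seed=5)
        c = dr.simulate_mixture(exp_model, 1, seed=6)
        assert a == b
        assert a != c


class TestSerialization:
    def test_json_round_trip(self, ph_models):
        m0, _ = ph_models
        back = dr.MixtureWeibullModel.from_json(m0.to_json())
        assert back.components == m0.components
        assert back.weights == m0.weights
        np.testing.assert_allclose(back.covariance, m0.covariance)
        assert back.log_lik == m0.log_lik
        assert back.n == m0.n and back.n_events == m0.n_events
        assert back.meta["seed"] == m0.meta["seed"]
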