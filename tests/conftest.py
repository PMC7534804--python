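import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dynrmst as dr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_dataset():
    """Minimal valid two-arm table: [(1,1,A),(2,0,A),(1.5,1,B),(3,1,B)], control A."""
    return dr.SurvivalDataset(
        time=[1.0, 2.0, 1.5, 3.0],
        event=[1, 0, 1, 1],
        arm=["A", "A", "B", "B"],
        control_label="A",
    )


@pytest.fixture
def exp_model():
    """Unit exponential: single Weibull component, scale 1, shape 1."""
    return dr.MixtureWeibullModel(components=((1.0, 1.0),), weights=(1.0,))


@pytest.fixture(scope="session")
def ph_trial():
    sc = dr.preset("ph", n_per_arm=400, seed=11)
    return sc, dr.simulate_trial(sc)


@pytest.fixture(scope="session")
def ph_models(ph_trial):
    _, ds = ph_trial
    m0 = dr.fit_mixture(ds.control, n_components=1, n_starts=3, seed=5)
    m1 = dr.fit_mixture(ds.treatment, n_components=1, n_starts=3, seed=6)
    return m0, m1


@pytest.fixture(scope="session")
def delayed_fit():
    """A 2000/arm delayed-effect trial with per-arm fits at the correct
    component counts; reused by several estimation tests."""
    sc = dr.preset("delayed", n_per_arm=2000, seed=3)
    ds = dr.simulate_trial(sc)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m0 = dr.fit_mixture(ds.control, n_components=1, n_starts=3, seed=1)
        m1 = dr.fit_mixture(ds.treatment, n_components=2, n_starts=4, seed=2)
    return sc, ds, m0, m1


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
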