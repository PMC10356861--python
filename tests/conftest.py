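import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def labeled_experiment():
    """Noisy triplicate labeled incubation with calibrated true rates."""
    from tauflux.simulate import calibrated_labeled_experiment

    return calibrated_labeled_experiment(seed=1)


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Same design with measurement noise switched off."""
    from tauflux.simulate import calibrated_labeled_experiment

    return calibrated_labeled_experiment(seed=3, noise_cv=0.0, atpct_noise_sd=0.0)
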