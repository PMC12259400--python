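import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import taxiv

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def calib_truth():
    """Strong-instrument preset at a small unit-test size."""
    return taxiv.load_preset("calibration", n_individuals=8000, seed=11)


@pytest.fixture(scope="session")
def calib_study(calib_truth):
    individuals, taxes = taxiv.simulate_study(calib_truth)
    return individuals, taxes


@pytest.fixture(scope="session")
def calib_data(calib_study):
    individuals, taxes = calib_study
    adults = individuals.loc[~individuals["negative_control"]]
    return taxiv.link_and_filter(adults, taxes)


@pytest.fixture(scope="session")
def paperlike_truth():
    return taxiv.load_preset("paperlike")


def make_dataset(preset="calibration", n=20000, seed=0, adults_only=True, **overrides):
    truth = taxiv.load_preset(preset, n_individuals=n, seed=seed, **overrides)
    individuals, taxes = taxiv.simulate_study(truth)
    frame = individuals.loc[~individuals["negative_control"]] if adults_only else individuals
    return truth, frame, taxes, taxiv.link_and_filter(frame, taxes)
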