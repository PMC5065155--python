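import numpy as np
import pytest
from hypothesis import settings

import dsbrepair as d
from dsbrepair import reference

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def d1_spec():
    """Wild-type dataset skeleton (20 Gy, all three channels full)."""
    return d.default_dataset_specs()["D1"]


@pytest.fixture(scope="session")
def d5_spec():
    """Ku-deficient dataset skeleton (80 Gy, slow + intermediate only)."""
    return d.default_dataset_specs()["D5"]


@pytest.fixture(scope="session")
def d1_rates():
    return reference.median_rate_params("D1")


@pytest.fixture(scope="session")
def d5_rates():
    return reference.median_rate_params("D5")


@pytest.fixture(scope="session")
def tiny_spec():
    """A fast-to-simulate single-dataset configuration for SMC tests.

    Low dose (few breaks) and a short grid keep a full SMC run in the
    hundreds of milliseconds.
    """
    table = d.default_pathway_config()
    return d.DatasetSpec(
        id="D1", dose_gy=4.0, phase="asynchronous",
        timepoints=np.array([0.0, 0.25, 1.0, 4.0, 24.0]),
        pathways=table["D1"],
    ).validate()


def make_observed(spec, rates, seed, noise_sd=0.0):
    """Attach a (optionally noisy) simulated observation to a spec."""
    rng = np.random.default_rng(seed)
    traj = d.simulate_dataset(spec, rates, seed=int(rng.integers(2**32)))
    curve = d.measured_curve(traj)
    if noise_sd > 0:
        curve = np.clip(curve + rng.normal(0, noise_sd, curve.shape), 0, None)
    return spec.with_observed(curve).validate()
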