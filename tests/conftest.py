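import numpy as np
import pytest
from hypothesis import settings

import tvbold as tb

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def task_design():
    return tb.TaskDesign()


def bold_like_series(rng, n, F, noise_sd=200.0, spike_prob=0.02, spike_sd=2000.0):
    """Raw-magnitude BOLD-like series: baseline + noise + sparse spikes."""
    base = rng.uniform(8000.0, 12000.0, size=(n, 1))
    out = base + rng.normal(0.0, noise_sd, size=(n, F))
    out += (rng.random((n, F)) < spike_prob) * rng.normal(0.0, spike_sd, (n, F))
    return out


@pytest.fixture(scope="session")
def small_task_phantom(task_design):
    spec = tb.PhantomSpec(dims=(6, 6, 2), design=task_design, seed=11)
    series, truth = tb.generate_phantom(spec)
    return spec, series, truth


@pytest.fixture(scope="session")
def noise_free_phantom(task_design):
    spec = tb.PhantomSpec(dims=(4, 4, 1), design=task_design,
                          noise_sd=0.0, spike_prob=0.0, seed=3)
    series, truth = tb.generate_phantom(spec)
    return spec, series, truth
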