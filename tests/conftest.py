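import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from sigprof import synthetic, traces


@pytest.fixture(scope="session")
def ca_set_noiseless():
    """Small noiseless Ca²⁺ trace set with ground truth."""
    return synthetic.gen_ca_traces(n_cells=12, noise_sd=0.0, seed=101)


@pytest.fixture(scope="session")
def camp_set_noisy():
    """Small noisy cAMP trace set with ground truth."""
    return synthetic.gen_camp_traces(n_cells=30, noise_sd=0.05, seed=202)


@pytest.fixture(scope="session")
def aligned_camp_noisy(camp_set_noisy):
    ts, gt = camp_set_noisy
    return ts.map(traces.align_to_stimulus), gt


def make_trace(dff, dt=2.0, stimulus_time=0.0, cell_id="c0", **kw):
    dff = np.asarray(dff, float)
    return traces.Trace(
        cell_id=cell_id,
        time=np.arange(dff.size) * dt,
        dff=dff,
        stimulus_time=stimulus_time,
        **kw,
    )
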