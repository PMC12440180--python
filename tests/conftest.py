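import numpy as np
import pytest
from hypothesis import settings

from glomlearn.synthetic import SyntheticSessionSpec, generate_trial_traces

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def make_session(
    n_rois=4,
    n_trials_per_odor=5,
    noise_sd=0.0,
    amplitudes=None,
    latencies=None,
    seed=0,
    **kwargs,
):
    """Small synthetic session; amplitudes/latencies are (n_rois, 2) maps."""
    spec = SyntheticSessionSpec(
        n_rois=n_rois,
        n_trials_per_odor=n_trials_per_odor,
        noise_sd=noise_sd,
        amplitude_map=amplitudes,
        latency_map=latencies,
        rng_seed=seed,
        **kwargs,
    )
    return generate_trial_traces(spec)


@pytest.fixture
def noiseless_session():
    """3 ROIs: CS+ responder, CS- responder, silent; no noise."""
    amplitudes = np.array([[0.5, 0.0], [0.0, 0.3], [0.0, 0.0]])
    latencies = np.array([[3, 0], [0, 5], [0, 0]])
    return make_session(
        n_rois=3, amplitudes=amplitudes, latencies=latencies, seed=11
    )
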