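import pytest

from ftcdlat.io_formats import PipelineConfig
from ftcdlat.pipeline import process_participant
from ftcdlat.synthetic import SimulationConfig, simulate_recording


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_sim_cfg():
    """Generator settings with noise, drift and artifacts switched off."""
    return SimulationConfig(
        noise_sd_pct=0.0,
        drift_sd_pct=0.0,
        spike_prob_per_trial=0.0,
        dropout_prob_per_trial=0.0,
        rng_seed=7,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_sim_cfg):
    return simulate_recording(clean_sim_cfg)


@pytest.fixture(scope="session")
def clean_result(clean_recording, cfg):
    rec, truth = clean_recording
    return process_participant(rec, cfg), truth


@pytest.fixture(scope="session")
def default_recording():
    """One participant under the default (noisy) study conditions."""
    return simulate_recording(SimulationConfig(rng_seed=42))


@pytest.fixture(scope="session")
def default_result(default_recording, cfg):
    rec, truth = default_recording
    return process_participant(rec, cfg), truth
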