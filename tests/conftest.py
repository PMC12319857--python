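import numpy as np
import pytest

from mrsglm.core import AcquisitionParams, TaskDesign
from mrsglm import synthdata as sd


@pytest.fixture(scope="session")
def params() -> AcquisitionParams:
    """Study-like acquisition: 2048 points, 2000 Hz, 3 T proton carrier."""
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_task() -> TaskDesign:
    """A compressed rest/task/rest design: 60/120/120 s -> 150 transients."""
    return TaskDesign(rest1_s=60.0, task_s=120.0, rest2_s=120.0)


@pytest.fixture(scope="session")
def study_task() -> TaskDesign:
    return TaskDesign()


@pytest.fixture(scope="session")
def small_clean_scan(params, small_task):
    """150-transient noiseless scan with the default resonance table."""
    table = sd.default_table(0, 0, 0)
    return sd.simulate_scan(table, sd.no_confounds(), params, small_task,
                            n_transients=150, seed=7)


@pytest.fixture(scope="session")
def small_noisy_scan(params, small_task):
    """150-transient scan at single-shot SNR ~31 with alignment jitter."""
    table = sd.default_table(0, 0, 0)
    conf = sd.no_confounds(noise_sd=sd.calibrate_noise(table, params, 31.0))
    conf.freq_jitter_sd_hz = 1.0
    conf.phase_jitter_sd_deg = 5.0
    return sd.simulate_scan(table, conf, params, small_task,
                            n_transients=150, seed=8)
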