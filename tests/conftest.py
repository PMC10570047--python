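import numpy as np
import pytest

import rlooptrace as rl


@pytest.fixture(scope="session")
def optics():
    return rl.OpticsParams()


@pytest.fixture(scope="session")
def noiseless():
    return rl.OpticsParams(noise_sd=0.0, k_bleach=0.0)


@pytest.fixture(scope="session")
def cfg(optics):
    return rl.ClassifyConfig.from_optics(optics)


@pytest.fixture(scope="session")
def cfg_noiseless(noiseless):
    return rl.ClassifyConfig.from_optics(noiseless)


@pytest.fixture(scope="session")
def dt1_calls(optics, cfg):
    """Classified DT1 cohort reused across fraction/timing tests."""
    kp = rl.preset_kinetics("DT1")
    trajs = rl.simulate_cohort("DT1", kp, 800, seed=101)
    traces = rl.render_cohort(trajs, optics, seed=102)
    calls = rl.classify_cohort(traces, cfg)
    return trajs, calls


def three_sd_band(p: float, n: int) -> float:
    return 3.0 * np.sqrt(p * (1 - p) / n)
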