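import numpy as np
import pytest

from albring.world import Cue, Environment


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def fig2_env():
    """Standard two-cue scenery: bimodal narrow red N/S, broad blue East."""
    cues = (
        Cue("red", "bimodal", (90.0, -90.0), kappa=20.0),
        Cue("blue", "broad", (0.0,), kappa=20.0, width=90.0),
    )
    return Environment("fig2", cues, ("red", "blue", "green"))


@pytest.fixture(scope="session")
def calibrated_spec():
    """A velocity-calibrated default attractor (cached for the session)."""
    from albring.hd_circuit import AttractorSpec, calibrate_velocity_gain

    spec = AttractorSpec()
    calibrate_velocity_gain(spec)
    return spec
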