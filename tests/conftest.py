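import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def rc_params():
    """A plain RC cell (no voltage-gated conductances)."""
    from opcephys.simulate import MembraneModelParams

    return MembraneModelParams(
        rs_mohm=10.0, cm_pf=30.0, g_leak_ns=5.0, e_leak_mv=-74.0,
        g_kir_ns=0.0, g_out_ns=0.0,
    )


@pytest.fixture(scope="session")
def rc_bundle(rc_params):
    from opcephys.simulate import simulate_voltage_clamp

    return simulate_voltage_clamp(rc_params, noise_rms_pa=0.0, seed=0)
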