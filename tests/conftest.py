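import numpy as np
import pytest

from killfrac import DimensionlessParams, default_bolus_table, run_kill_curve


@pytest.fixture(scope="session")
def bolus_table():
    """Shared model-bolus surrogate (built once per session, ~30 s)."""
    return default_bolus_table()


@pytest.fixture(scope="session")
def curve_intermediate():
    """Reference-resolution kill curve at r_b/L = 0.1, BVF = 0.01, t' in [0, 10]."""
    return run_kill_curve(DimensionlessParams(rb_over_L=0.1, BVF=0.01), t_end=10.0, dt=1e-3, n_nodes=2001)


@pytest.fixture(scope="session")
def curve_high_bvf():
    """Reference-resolution kill curve at r_b/L = 0.1, BVF = 0.05, t' in [0, 10]."""
    return run_kill_curve(DimensionlessParams(rb_over_L=0.1, BVF=0.05), t_end=10.0, dt=1e-3, n_nodes=2001)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
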