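import numpy as np
import pandas as pd
import pytest

from vermis.config import RunConfig
from vermis.synth import SessionConfig, generate_session


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def grid(config) -> np.ndarray:
    edges = np.arange(
        config.mf_grid_start_ms, config.mf_grid_stop_ms + config.bin_ms, config.bin_ms
    )
    return edges[:-1] + config.bin_ms / 2.0


@pytest.fixture(scope="session")
def small_session(config):
    """A small full session (with traces) shared across tests."""
    cfg = SessionConfig(
        n_trials=80,
        seed=42,
        n_mf_bt=2, n_mf_llb=3, n_mf_slb=2,
        n_pc_burst=2, n_pc_pause=2, n_pc_burst_pause=2, n_pc_pause_burst=2,
    )
    bundle, units, truth = generate_session(cfg, config)
    return cfg, bundle, units, truth


@pytest.fixture(scope="session")
def medium_session(config):
    """A 300-trial session without traces, for classification/CS tests."""
    cfg = SessionConfig(n_trials=300, seed=7)
    bundle, units, truth = generate_session(cfg, config, with_traces=False)
    return cfg, bundle, units, truth


@pytest.fixture()
def flat_trials() -> pd.DataFrame:
    """Hand-made kinematics table without generator bookkeeping columns."""
    rng = np.random.default_rng(3)
    pv = rng.uniform(400, 550, 40)
    return pd.DataFrame(
        dict(
            trial_index=np.arange(40),
            type="centrifugal",
            direction="right",
            pv=pv,
            duration_ms=15.0 / (0.62 * pv) * 1000.0,
            amplitude=15.0,
            error_direction="none",
            error_type="none",
        )
    )
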