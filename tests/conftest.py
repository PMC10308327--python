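import warnings

import numpy as np
import pytest

from crystallokin.synthetic_data import (SimTraceConfig,
                                         simulate_current_trace)


@pytest.fixture(autouse=True)
def _quiet_baseline_warnings():
    """Short-baseline advisories are irrelevant to most tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*baselines.*", category=UserWarning)
        yield


@pytest.fixture(scope="session")
def default_trace():
    """One default simulated trace shared across read-only tests."""
    return simulate_current_trace(SimTraceConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
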