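"""Shared fixtures: simulated subjects at full and tiny scale.

The full-size subject (288 trials, 25 channels, 250 Hz) is expensive to
simulate and preprocess, so it is built once per session and shared by
the simulator, preprocessing and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from clrnet.preprocess import preprocess_pipeline
from clrnet.simulate import SimConfig, simulate_subject


@pytest.fixture(scope="session")
def subject288():
    """Default study conditions: 288 trials, erd_depth=0.8, snr=4, seed 7."""
    cfg = SimConfig(seed=7)
    rec, gt = simulate_subject(cfg)
    return rec, gt, cfg


@pytest.fixture(scope="session")
def epochs288(subject288):
    rec, _, _ = subject288
    return preprocess_pipeline(rec)


@pytest.fixture(scope="session")
def tiny_subject():
    """12-trial subject for fast structural tests."""
    cfg = SimConfig(n_trials_per_class=3, seed=5)
    rec, gt = simulate_subject(cfg)
    return rec, gt, cfg


@pytest.fixture(scope="session")
def tiny_epochs(tiny_subject):
    rec, _, _ = tiny_subject
    return preprocess_pipeline(rec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
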