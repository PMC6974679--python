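"""Shared fixtures: small deterministic cohorts and signal helpers."""

from __future__ import annotations

import numpy as np
import pytest

from nmstate.pipeline import default_cohort_config
from nmstate.synthetic import generate_coupled_timeseries


@pytest.fixture(scope="session")
def tiny_cohort():
    """One subject per group, 60 s — enough for structural checks."""
    cfg = default_cohort_config(seed=11, n_subjects_per_group=1, duration=60.0)
    subjects, gt = generate_coupled_timeseries(cfg)
    return cfg, subjects, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def constant_lag_phases(
    lag: float, fs: float = 128.0, duration: float = 4.0, f: float = 20.0
) -> np.ndarray:
    """Two analytic phase rows with an exact constant relative lag."""
    t = np.arange(int(fs * duration)) / fs
    base = 2 * np.pi * f * t
    return np.vstack([base, base - lag])
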