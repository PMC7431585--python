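"""Shared fixtures.

The heavy fixture is ``recovery_cohort``: a full 20-subject simulated study
(study-scale 52-frequency wavelet family and 200-point time grid, 160 trials
per subject) analyzed end to end.  It is session-scoped so the parameter
recovery, follow-up statistics and cluster-test checks all reuse one run.
"""

from __future__ import annotations

import numpy as np
import pytest

import alphalat as al
from alphalat.config import PipelineConfig
from alphalat.simulate import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def design800():
    return al.generate_design(800, seed=5)


@pytest.fixture(scope="session")
def fast_params():
    """Small, fast simulation settings for unit tests."""
    return SimParams(n_subjects=4, n_trials=32, lapse_rate=0.0, seed=9)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-resolution analysis settings for unit tests."""
    return PipelineConfig(f_min_hz=6.0, f_max_hz=20.0, n_freqs=10,
                          time_grid=80, n_perm=100, seed=3)


@pytest.fixture(scope="session")
def recovery_cohort():
    """Full study-scale recovery run: 20 subjects, injected ALI +/-0.2."""
    cfg = PipelineConfig(seed=11)
    params = SimParams(n_subjects=20, n_trials=160)
    cohort = al.run_cohort(params, cfg, seed=42)
    analysis = al.analyze_cohort(cohort, cfg)
    return cohort, analysis, cfg, params
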