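"""Shared fixtures: small simulation parameter sets and rendered movies.

Expensive artifacts (the standard synthetic movie and its segmentation)
are session-scoped so several test modules can share one render.
"""

import numpy as np
import pytest

from pulse_coupler.en_core import ExcitableParams
from pulse_coupler.fdm_imaging import frame_difference_pct, segment_cell
from pulse_coupler.synthetic_data import default_config, synth_movie


@pytest.fixture
def small_params() -> ExcitableParams:
    """A 60-point ring: same dynamics, much cheaper than the full grid."""
    return ExcitableParams(n_points=60, sigma_N=0.0)


@pytest.fixture(scope="session")
def standard_movie():
    """Noise-free standard movie (4 protrusions, 2 flashes) + ground truth."""
    cfg = default_config(seed=11)
    stacks, gt = synth_movie(cfg)
    return cfg, stacks, gt


@pytest.fixture(scope="session")
def standard_analysis(standard_movie):
    """Segmentation + FDM of the standard movie's protrusion channel."""
    _, stacks, _ = standard_movie
    stack = stacks["protrusion"]
    mask = segment_cell(stack)
    fdm = frame_difference_pct(stack, interval_minutes=6.0, avg_window=3)
    return stack, mask, fdm


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
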