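"""Shared fixtures: small synthetic trials and a session-scoped study."""

import numpy as np
import pytest

from bowkin import synthetic as syn
from bowkin.mocap_io import MarkerFrameSeries


@pytest.fixture(scope="session")
def teacher_ex1():
    """Teacher demonstration of exercise 1 (8 full strokes, 16 s)."""
    return syn.generate_teacher(syn.script_for(1))


@pytest.fixture(scope="session")
def teacher_short():
    """A short teacher trial (2 strokes) for fast marker-level tests."""
    return syn.generate_teacher(syn.script_for(1, tempo=1.5, repeats=1))


@pytest.fixture(scope="session")
def study12():
    """Default full-size synthetic study: 12 participants per group,
    3 exercises x 3 stages, analysed through the marker-level pipeline."""
    return syn.simulate_study(n_per_group=12, seed=20260924 % 2**31)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_series(positions, rate=120.0, labels=None, occluded=None, start_time=0.0):
    positions = np.asarray(positions, dtype=float)
    if labels is None:
        labels = [f"M{j}" for j in range(positions.shape[1])]
    return MarkerFrameSeries(labels, positions, rate, occluded, start_time)


@pytest.fixture()
def linear_series():
    """Three markers moving on straight lines, 60 frames at 120 Hz."""
    t = np.arange(60) / 120.0
    pos = np.empty((60, 3, 3))
    for j, (v, off) in enumerate([(10.0, 0.0), (-5.0, 100.0), (2.0, -50.0)]):
        pos[:, j, 0] = off + v * t * 1000
        pos[:, j, 1] = off + 1.0 + j
        pos[:, j, 2] = off - 2.0 * j
    return make_series(pos)
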