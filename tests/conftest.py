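"""Shared fixtures: small synthetic sessions on a 200 Hz grid.

Unit tests run at 200 Hz (5 ms step) to keep the suite fast; the grid
convention is identical at any rate and the acceptance suite exercises
1000 Hz where the printed sample counts require it.
"""

import numpy as np
import pytest

from overlapfrp import (
    TimeWindow,
    extract_epochs,
    make_fixture,
    select_ranks,
)

FS = 200.0


@pytest.fixture(scope="session")
def mid_session():
    """Noiseless mid-exploration session (fixation-locked, overlapping)."""
    return make_fixture("mid_exploration", seed=7, n_trials=30, sample_rate_hz=FS)


@pytest.fixture(scope="session")
def mid_epochs(mid_session):
    locks = select_ranks(mid_session.events, 3, 9, 3, seed=17)
    return extract_epochs(
        mid_session.recording,
        mid_session.events,
        "fixation",
        TimeWindow(-660, 1010, FS),
        locks,
    )


@pytest.fixture(scope="session")
def fonly_session():
    return make_fixture("first_order_only", seed=3, n_trials=60, sample_rate_hz=FS)


@pytest.fixture(scope="session")
def fonly_epochs(fonly_session):
    meta = fonly_session.meta
    locks = select_ranks(
        fonly_session.events, *meta["rank_range"], meta["draws"], seed=5
    )
    return extract_epochs(
        fonly_session.recording,
        fonly_session.events,
        "fixation",
        TimeWindow(*meta["epoch_window"], FS),
        locks,
    )


@pytest.fixture(scope="session")
def onset_session():
    return make_fixture("onset_three_class", seed=11, n_trials=15, sample_rate_hz=FS)


@pytest.fixture(scope="session")
def onset_epochs(onset_session):
    return extract_epochs(
        onset_session.recording,
        onset_session.events,
        "stimulus",
        TimeWindow(-200, 1500, FS),
    )


def brute_force_convolution(mass, mass_start, values, val_start, out_start, out_n):
    """O(N^2) reference convolution on the sample grid."""
    values = np.atleast_2d(values)
    if values.shape[0] == 1:
        values = values.T
    out = np.zeros((out_n, values.shape[1]))
    for j in range(out_n):
        t = out_start + j
        for i, m in enumerate(mass):
            k = t - (mass_start + i) - val_start
            if 0 <= k < values.shape[0]:
                out[j] += m * values[k]
    return out
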