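"""Shared simulation fixtures.

The kinetic simulations are the expensive part of the suite, so each preset
experiment is run once per session and shared between the unit tests and
the acceptance tests.
"""

import dataclasses

import pytest

from hrdquant import frap, simulate as sim


@pytest.fixture(scope="session")
def retentive_params():
    return sim.preset("retentive", bleach_depth=0.1)


@pytest.fixture(scope="session")
def retentive_partial(retentive_params):
    """Partial (half-focus) bleach of the largest chromocenter, 100 s."""
    roi = sim.chromocenter_roi(retentive_params, 0, half=True)
    frames, series = sim.simulate_frap(
        retentive_params, roi, t_end=100.0, frame_interval=2.0,
        roi_kind="partial", record_frames=True,
    )
    return frames, series


@pytest.fixture(scope="session")
def retentive_partial_curve(retentive_partial):
    return frap.process_series(retentive_partial[1])


@pytest.fixture(scope="session")
def retentive_total_curve(retentive_params):
    roi = sim.chromocenter_roi(retentive_params, 0)
    _, series = sim.simulate_frap(
        retentive_params, roi, t_end=100.0, frame_interval=2.0, record_frames=False
    )
    return frap.process_series(series)


@pytest.fixture(scope="session")
def retentive_ifrap_curve(retentive_params):
    """30-minute inverse FRAP (whole nucleus bleached except one focus)."""
    params = dataclasses.replace(retentive_params, bleach_depth=0.0)
    _, series = sim.simulate_ifrap(
        params, t_end=1800.0, frame_interval=30.0, record_frames=False
    )
    return frap.process_ifrap(series)


@pytest.fixture(scope="session")
def exchanging_total_curve():
    params = sim.preset("exchanging", bleach_depth=0.1)
    roi = sim.chromocenter_roi(params, 0)
    _, series = sim.simulate_frap(
        params, roi, t_end=100.0, frame_interval=2.0, record_frames=False
    )
    return frap.process_series(series)


@pytest.fixture(scope="session")
def unbound_total_curve():
    params = sim.preset("unbound", bleach_depth=0.1)
    roi = sim.chromocenter_roi(params, 0)
    _, series = sim.simulate_frap(
        params, roi, t_end=20.0, frame_interval=0.5, record_frames=False
    )
    return frap.process_series(series)
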