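"""FRAP quantification: normalization chain, fitting, iFRAP arithmetic."""

import dataclasses

import numpy as np
import pytest

from hrdquant import frap, simulate as sim
from hrdquant.simulate import FrapSeries


def make_series(times, bleach, nucleus=None, background=None, bleach_index=2,
                roi_kind="total"):
    times = np.asarray(times, dtype=float)
    n = times.size
    return FrapSeries(
        times=times,
        traces={
            "bleach": np.asarray(bleach, dtype=float),
            "nucleus": np.full(n, 100.0) if nucleus is None else np.asarray(nucleus, float),
            "background": np.zeros(n) if background is None else np.asarray(background, float),
        },
        bleach_index=bleach_index,
        roi_kind=roi_kind,
    )


# --------------------------------------------------------------- chain

def test_background_correct_subtracts_per_frame():
    s = make_series([0, 1, 2, 3], [50, 52, 54, 56], background=[10, 10, 10, 10])
    out = frap.background_correct(s)
    np.testing.assert_array_equal(out.traces["bleach"], [40, 42, 44, 46])
    np.testing.assert_array_equal(out.traces["background"], 0.0)


def test_background_correct_requires_background_roi():
    s = make_series([0, 1, 2, 3], [1, 2, 3, 4])
    del s.traces["background"]
    with pytest.raises(ValueError, match="background"):
        frap.background_correct(s)


def test_scanning_normalization_undoes_acquisition_decay():
    # whole nucleus decays 1% per frame while the true ROI signal is constant
    n = 12
    decay = 0.99 ** np.arange(n)
    s = make_series(np.arange(n), 60.0 * decay, nucleus=100.0 * decay)
    out = frap.normalize_scanning(s)
    anchor = s.bleach_index
    np.testing.assert_allclose(out.traces["bleach"], 60.0 * decay[anchor], rtol=1e-12)


def test_scanning_normalization_identity_for_constant_nucleus():
    s = make_series(np.arange(6), [9, 9, 3, 4, 5, 6])
    out = frap.normalize_scanning(s)
    np.testing.assert_array_equal(out.traces["bleach"], s.traces["bleach"])


def test_scanning_normalization_rejects_nonpositive_nucleus():
    s = make_series(np.arange(4), [1, 1, 1, 1], nucleus=[100, 100, 0, 100])
    with pytest.raises(ValueError, match="frame"):
        frap.normalize_scanning(s)


def test_relative_fluorescence_prebleach_equals_one():
    s = make_series(np.arange(6), [80, 80, 24, 30, 40, 50])
    curve = frap.relative_fluorescence(s)
    assert curve.relative_fluorescence[s.bleach_index - 1] == 1.0
    assert 0 <= curve.relative_fluorescence[s.bleach_index] < 1


def test_relative_fluorescence_of_unbleached_roi_is_unity():
    s = make_series(np.arange(6), np.full(6, 42.0))
    curve = frap.relative_fluorescence(s)
    np.testing.assert_allclose(curve.relative_fluorescence, 1.0)


def test_no_dynamics_curve_sits_at_bleach_depth():
    s = make_series(np.arange(8), [100, 100, 30, 30, 30, 30, 30, 30])
    curve = frap.process_series(s)
    np.testing.assert_allclose(curve.post_values, 0.3, rtol=1e-12)


def test_pipeline_is_identity_up_to_prebleach_scale():
    """Zero background + constant nuclear trace: the full chain only divides
    by the pre-bleach intensity."""
    vals = np.array([90.0, 90.0, 27.0, 40.0, 55.0, 63.0])
    s = make_series(np.arange(6), vals)
    curve = frap.process_series(s)
    np.testing.assert_allclose(curve.relative_fluorescence, vals / 90.0, rtol=1e-12)


def test_acquisition_bleaching_corrected_within_one_percent():
    """A simulation with 0.5%/frame scanning photobleaching matches the
    clean simulation after normalization."""
    p = sim.preset("exchanging", bleach_depth=0.1)
    roi = sim.chromocenter_roi(p, 0)
    kwargs = dict(t_end=30.0, frame_interval=1.0, record_frames=False)
    _, clean = sim.simulate_frap(p, roi, **kwargs)
    _, bleached = sim.simulate_frap(p, roi, acq_bleach_per_frame=0.005, **kwargs)
    c_clean = frap.process_series(clean)
    c_corr = frap.process_series(bleached)
    np.testing.assert_allclose(
        c_corr.relative_fluorescence, c_clean.relative_fluorescence, rtol=0.01
    )


# --------------------------------------------------------------- fitting

def _curve_from_model(f0, a1, tau1, a2, tau2, t_end=120.0, dt=0.5, noise_sd=0.0, seed=0):
    t_post = np.arange(0.0, t_end + dt / 2, dt)
    y_post = f0 + a1 * (1 - np.exp(-t_post / tau1)) + a2 * (1 - np.exp(-t_post / tau2))
    if noise_sd:
        y_post = y_post + np.random.default_rng(seed).normal(0, noise_sd, y_post.size)
    times = np.concatenate([[-2 * dt, -dt], t_post])
    values = np.concatenate([[1.0, 1.0], y_post])
    return frap.FrapCurve(times=times, relative_fluorescence=values, bleach_index=2)


def test_double_exponential_fit_exact_on_noiseless_curve():
    truth = dict(f0=0.2, a1=0.5, tau1=3.0, a2=0.3, tau2=40.0)
    fit = frap.fit_double_exponential(_curve_from_model(**truth))
    assert fit.fit_rss < 1e-10
    for name in ("a1", "tau1", "a2", "tau2"):
        assert getattr(fit, name) == pytest.approx(truth[name], rel=0.01)
    assert fit.mobile_fraction == pytest.approx(1.0, rel=0.02)


def test_double_exponential_fit_under_replicate_noise():
    """Parameters recovered within 10% at noise matching ~15-cell averaging."""
    truth = dict(f0=0.2, a1=0.5, tau1=3.0, a2=0.3, tau2=40.0)
    fit = frap.fit_double_exponential(_curve_from_model(noise_sd=0.01, seed=4, **truth))
    for name in ("a1", "tau1", "a2", "tau2"):
        assert getattr(fit, name) == pytest.approx(truth[name], rel=0.10)


def test_flat_postbleach_curve_has_zero_mobile_fraction():
    fit = frap.fit_double_exponential(_curve_from_model(0.3, 0.0, 1.0, 0.0, 10.0))
    assert fit.mobile_fraction == pytest.approx(0.0, abs=1e-6)


def test_fit_requires_enough_frames():
    c = _curve_from_model(0.2, 0.5, 3.0, 0.3, 40.0, t_end=2.0, dt=0.5)
    with pytest.raises(ValueError, match="8"):
        frap.fit_double_exponential(c)


# --------------------------------------------------------------- recovery_at

def test_recovery_at_zero_and_flat_curves():
    flat = _curve_from_model(0.3, 0.0, 1.0, 0.0, 10.0)
    assert frap.recovery_at(flat, 0.0) == 0.0
    assert frap.recovery_at(flat, 50.0) == pytest.approx(0.0, abs=1e-12)


def test_recovery_at_rejects_out_of_range():
    c = _curve_from_model(0.2, 0.5, 3.0, 0.3, 40.0, t_end=60.0)
    with pytest.raises(ValueError, match="outside"):
        frap.recovery_at(c, 100.0)


# --------------------------------------------------------------- kymograph

def test_kymograph_static_image_columns_identical():
    img = np.outer(np.arange(20.0), np.ones(20)) + 5
    frames = [sim.ImagingField(data=img, pixel_size=0.1, time=float(t)) for t in range(4)]
    k = frap.kymograph(frames, ((2, 3), (15, 3)))
    for j in range(1, 4):
        np.testing.assert_array_equal(k[:, j], k[:, 0])


def test_kymograph_rejects_degenerate_line():
    img = np.ones((8, 8))
    frames = [sim.ImagingField(data=img, pixel_size=0.1)]
    with pytest.raises(ValueError, match="zero-length"):
        frap.kymograph(frames, ((2, 2), (2, 2)))


def test_partial_bleach_kymograph_converges_without_phantom(retentive_partial):
    """The bleached half's profile rises and the unbleached half's falls,
    converging with no step at the bleach boundary."""
    frames, series = retentive_partial
    cy, cx, r = sim.preset("retentive").chromocenters[0]
    k = frap.kymograph(frames, ((cy, cx - r + 1.5), (cy, cx + r - 1.5)))
    npos = k.shape[0]
    left = slice(0, npos // 2 - 1)     # bleached half (x <= cx)
    right = slice(npos // 2 + 2, npos)  # spared half
    i0 = series.bleach_index
    assert k[left, -1].mean() > 1.5 * k[left, i0].mean()
    assert k[right, -1].mean() < 0.8 * k[right, i0].mean()
    final = k[:, -1]
    rel_spread = (final.max() - final.min()) / final.mean()
    assert rel_spread < 0.15  # remixed: no residual step across the boundary


# --------------------------------------------------------------- iFRAP

def _linear_ifrap_curve(rate_pct_per_min=0.7, t_end=1800.0, dt=30.0):
    t_post = np.arange(0.0, t_end + dt / 2, dt)
    values = 1.0 - (rate_pct_per_min / 100.0) * t_post / 60.0
    times = np.concatenate([[-2 * dt, -dt], t_post])
    vals = np.concatenate([[1.0, 1.0], values])
    return frap.FrapCurve(times=times, relative_fluorescence=vals,
                          bleach_index=2, roi_kind="inverse")


def test_ifrap_worked_example_turnover_and_ratio():
    """A 0.7%/min efflux extrapolates to ~2.4 h complete turnover and,
    against ~30 s internal remixing, a ~290-fold rate difference."""
    curve = _linear_ifrap_curve(0.7)
    res = frap.ifrap_efflux(curve, window=1800.0, internal_equilibration=30.0)
    assert res.efflux_rate == pytest.approx(0.7, rel=1e-9)
    assert res.turnover_time == pytest.approx(100.0 / 0.7 / 60.0, rel=1e-9)
    assert round(res.turnover_time, 1) == 2.4
    assert res.equilibration_ratio == pytest.approx(285.7, rel=1e-3)
    assert round(res.equilibration_ratio, -1) == 290.0


def test_ifrap_arithmetic_identities():
    res = frap.ifrap_efflux(_linear_ifrap_curve(1.4), window=1800.0,
                            internal_equilibration=45.0)
    # turnover (min) * rate (%/min) == 100%
    assert res.turnover_time * 60.0 * res.efflux_rate == pytest.approx(100.0)
    assert res.equilibration_ratio == pytest.approx(res.turnover_time * 3600.0 / 45.0)


def test_ifrap_constant_curve_flagged():
    c = _linear_ifrap_curve(0.0)
    res = frap.ifrap_efflux(c, window=1800.0)
    assert res.efflux_rate == 0.0
    assert np.isnan(res.turnover_time)
    assert "no_efflux" in res.flags


def test_ifrap_influx_warns_and_zeroes():
    c = _linear_ifrap_curve(-0.5)
    with pytest.warns(UserWarning, match="influx"):
        res = frap.ifrap_efflux(c, window=1800.0)
    assert res.efflux_rate == 0.0


def test_ifrap_window_must_fit_record():
    with pytest.raises(ValueError, match="window"):
        frap.ifrap_efflux(_linear_ifrap_curve(0.7, t_end=600.0), window=1800.0)


# --------------------------------------------------------- equilibration time

def test_internal_equilibration_single_exponential_is_three_tau():
    tau = 7.0
    c = _curve_from_model(0.2, 0.8, tau, 0.0, tau, t_end=60.0, dt=0.25)
    t95 = frap.internal_equilibration_time(c, threshold=0.95)
    assert t95 == pytest.approx(-tau * np.log(0.05), abs=0.5)


def test_internal_equilibration_step_curve():
    times = np.arange(-2.0, 30.0)
    vals = np.where(times < 0, 1.0, np.where(times < 1, 0.2, 0.9))
    c = frap.FrapCurve(times=times, relative_fluorescence=vals, bleach_index=2)
    t = frap.internal_equilibration_time(c, threshold=0.9)
    assert t <= 1.5  # plateau reached at the first post-step frame


def test_internal_equilibration_rejects_unreached_plateau():
    c = _curve_from_model(0.2, 0.8, 200.0, 0.0, 200.0, t_end=30.0)
    with pytest.raises(ValueError, match="never reached"):
        frap.internal_equilibration_time(c, threshold=0.95)


def test_retentive_partial_bleach_remixes_in_tens_of_seconds(retentive_partial_curve):
    t_eq = frap.internal_equilibration_time(retentive_partial_curve, threshold=0.95)
    assert 10.0 <= t_eq <= 60.0


def test_averaging_returns_pointwise_mean_and_sd():
    c1 = _curve_from_model(0.2, 0.5, 3.0, 0.3, 40.0)
    c2 = _curve_from_model(0.4, 0.3, 3.0, 0.3, 40.0)
    mean, sd = frap.average_curves([c1, c2])
    np.testing.assert_allclose(
        mean.relative_fluorescence,
        (c1.relative_fluorescence + c2.relative_fluorescence) / 2,
    )
    assert np.all(sd >= 0)
    assert mean.meta["n_cells"] == 2
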