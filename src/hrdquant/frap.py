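"""FRAP and inverse-FRAP quantification.

Implements the standard confocal FRAP processing chain for nuclear
compartment experiments:

1. :func:`background_correct` -- subtract the per-frame background ROI mean
   from every ROI trace;
2. :func:`normalize_scanning` -- correct for acquisition photobleaching by
   rescaling the bleached-ROI trace with the whole-nucleus ratio,
   ``NormI(t_n) = I(t1)_nucleus / I(t_n)_nucleus * I(t_n)_ROI`` with ``t1``
   the first post-bleach frame;
3. :func:`relative_fluorescence` -- divide by the pre-bleach intensity so
   the curve equals 1 before the bleach;
4. :func:`fit_double_exponential` -- empirical double-term exponential
   recovery fit yielding amplitudes, time constants and the mobile fraction;
5. :func:`recovery_at` -- fractional recovery at fixed times (e.g. 5 s and
   100 s), referenced to the post-bleach minimum;
6. :func:`ifrap_efflux` / :func:`internal_equilibration_time` -- inverse-FRAP
   apparent efflux rate (%/min), extrapolated complete-turnover time, and
   the ratio of compartment turnover to internal remixing time;
7. :func:`kymograph` -- position x time intensity profile along a line.

The two normalization anchors follow different conventions on purpose: the
scanning correction is anchored at the first post-bleach frame while the
relative-fluorescence denominator is the pre-bleach intensity; both anchors
are explicit keyword arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import linregress
from skimage.measure import profile_line

from .simulate import FrapSeries, ImagingField

__all__ = [
    "FrapSeries",
    "FrapCurve",
    "FrapFit",
    "IFrapResult",
    "background_correct",
    "normalize_scanning",
    "relative_fluorescence",
    "process_series",
    "process_ifrap",
    "fit_double_exponential",
    "recovery_at",
    "kymograph",
    "ifrap_efflux",
    "internal_equilibration_time",
    "average_curves",
]


@dataclass
class FrapCurve:
    """Relative fluorescence versus time for one cell.

    ``times`` are in seconds on the acquisition clock; ``bleach_index``
    marks the first post-bleach frame (time is re-zeroed there for fitting).
    """

    times: np.ndarray
    relative_fluorescence: np.ndarray
    bleach_index: int
    roi_kind: str = "total"
    meta: dict = field(default_factory=dict)

    @property
    def post_times(self) -> np.ndarray:
        """Bleach-relative times of the post-bleach frames."""
        t0 = self.times[self.bleach_index]
        return self.times[self.bleach_index:] - t0

    @property
    def post_values(self) -> np.ndarray:
        return self.relative_fluorescence[self.bleach_index:]


@dataclass
class FrapFit:
    """Parameters of the double-term exponential recovery fit

    ``F(t) = F0 + a1*(1 - exp(-t/tau1)) + a2*(1 - exp(-t/tau2))``

    with ``tau1 <= tau2``.  ``mobile_fraction = (plateau - F0)/(1 - F0)``
    where ``plateau = F0 + a1 + a2``.
    """

    f0: float
    a1: float
    tau1: float
    a2: float
    tau2: float
    mobile_fraction: float
    recovery_5s: float
    recovery_100s: float
    fit_rss: float
    degraded: bool = False

    @property
    def plateau(self) -> float:
        return self.f0 + self.a1 + self.a2

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (
            self.f0
            + self.a1 * (1.0 - np.exp(-t / self.tau1))
            + self.a2 * (1.0 - np.exp(-t / self.tau2))
        )


@dataclass
class IFrapResult:
    """Inverse-FRAP summary.

    ``efflux_rate`` is the apparent efflux rate ER_app in %/min (negated
    OLS slope of percent intensity on minutes); ``turnover_time`` the
    extrapolated complete-turnover time in hours (100/rate, minutes ->
    hours); ``equilibration_ratio`` the turnover time in seconds divided by
    the internal remixing time.
    """

    efflux_rate: float
    turnover_time: float
    equilibration_ratio: float = float("nan")
    internal_equilibration_time: float = float("nan")
    flags: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# normalization chain
# ---------------------------------------------------------------------------

def background_correct(series: FrapSeries) -> FrapSeries:
    """Subtract the per-frame background mean from every ROI trace."""
    if "background" not in series.traces:
        raise ValueError("series has no background ROI")
    out = series.copy()
    bg = out.traces["background"]
    if "nucleus" in out.traces and np.any(bg > out.traces["nucleus"]):
        warnings.warn("background exceeds whole-nucleus intensity on some frames")
    for k in out.traces:
        out.traces[k] = out.traces[k] - bg
    out.meta["background_corrected"] = True
    return out


def normalize_scanning(
    series: FrapSeries, anchor: str = "post", roi: str = "bleach"
) -> FrapSeries:
    """Rescale the bleached-ROI trace by the whole-nucleus ratio.

    The anchor frame (default: first post-bleach frame, ``anchor="pre"``
    uses the last pre-bleach frame) defines the reference nucleus intensity;
    the correction factor is exactly 1 there.  Frames with non-positive
    whole-nucleus intensity are rejected.
    """
    if "nucleus" not in series.traces:
        raise ValueError("series has no whole-nucleus ROI")
    nuc = series.traces["nucleus"]
    bad = np.nonzero(nuc <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive whole-nucleus intensity at frame(s) {bad.tolist()}; "
            "cannot form the scanning-correction ratio"
        )
    idx = series.bleach_index if anchor == "post" else series.bleach_index - 1
    out = series.copy()
    out.traces[roi] = nuc[idx] / nuc * series.traces[roi]
    out.meta["scanning_anchor"] = anchor
    return out


def relative_fluorescence(
    series: FrapSeries, roi: str = "bleach", prebleach: str = "last"
) -> FrapCurve:
    """Divide the (corrected, normalized) ROI trace by its pre-bleach value.

    ``prebleach="last"`` uses the last frame before the bleach as the unit
    reference; ``"mean"`` averages all pre-bleach frames (more robust under
    noise).
    """
    if series.bleach_index < 1:
        raise ValueError("no pre-bleach frame in series")
    trace = series.traces[roi]
    pre = trace[: series.bleach_index]
    ref = pre[-1] if prebleach == "last" else pre.mean()
    if ref <= 0:
        raise ValueError("non-positive pre-bleach reference intensity")
    return FrapCurve(
        times=series.times.copy(),
        relative_fluorescence=trace / ref,
        bleach_index=series.bleach_index,
        roi_kind=series.roi_kind,
        meta=dict(series.meta),
    )


def process_series(series: FrapSeries, **kwargs) -> FrapCurve:
    """Full chain: background correction, scanning normalization, relative
    fluorescence."""
    return relative_fluorescence(
        normalize_scanning(background_correct(series)), **kwargs
    )


def process_ifrap(series: FrapSeries) -> FrapCurve:
    """Inverse-FRAP chain: spared-ROI intensity normalized to the whole cell.

    After background correction the spared-region trace is divided by the
    whole-nucleus trace frame-wise, then scaled so the first post-bleach
    frame equals 1 (= 100% of the compartment's post-bleach content).  The
    efflux slope of :func:`ifrap_efflux` is therefore in percent of the
    spared compartment per minute.
    """
    corr = background_correct(series)
    nuc = corr.traces["nucleus"]
    if np.any(nuc[corr.bleach_index:] <= 0):
        raise ValueError("non-positive whole-nucleus intensity post-bleach")
    ratio = corr.traces["bleach"] / nuc
    ref = ratio[corr.bleach_index]
    return FrapCurve(
        times=corr.times.copy(),
        relative_fluorescence=ratio / ref,
        bleach_index=corr.bleach_index,
        roi_kind="inverse",
        meta=dict(corr.meta),
    )


def average_curves(curves: list[FrapCurve]) -> tuple[FrapCurve, np.ndarray]:
    """Pointwise mean and standard deviation across replicate cells.

    All curves must share the same time base (frames are averaged by index,
    as when replicate cells are imaged with one protocol).
    """
    if not curves:
        raise ValueError("no curves to average")
    n = min(c.relative_fluorescence.size for c in curves)
    stack = np.vstack([c.relative_fluorescence[:n] for c in curves])
    mean = FrapCurve(
        times=curves[0].times[:n].copy(),
        relative_fluorescence=stack.mean(axis=0),
        bleach_index=curves[0].bleach_index,
        roi_kind=curves[0].roi_kind,
        meta={"n_cells": len(curves)},
    )
    sd = stack.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(n)
    return mean, sd


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------

_TAU_BOUNDS = (1e-3, 1e4)
_A_BOUNDS = (0.0, 1.5)


def _double_exp(theta, t):
    f0, a1, tau1, a2, tau2 = theta
    return f0 + a1 * (1.0 - np.exp(-t / tau1)) + a2 * (1.0 - np.exp(-t / tau2))


def fit_double_exponential(curve: FrapCurve, n_starts: int = 8) -> FrapFit:
    """Least-squares double-term exponential fit on the post-bleach frames.

    Time is re-zeroed at the bleach.  Amplitudes are bounded in [0, 1.5] and
    time constants in [1e-3, 1e4] s; ``n_starts`` initializations on a
    log-spaced (tau1, tau2) grid guard against local minima, tie-broken by
    lowest residual sum of squares.  If no start converges, a
    single-exponential fallback is returned flagged ``degraded``.
    """
    t = curve.post_times
    y = curve.post_values
    if t.size < 8:
        raise ValueError("need at least 8 post-bleach frames for a double-exponential fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("curve contains non-finite values")
    f0_init = float(y[0])
    amp = max(float(y[-1] - y[0]), 1e-6)
    t_span = max(float(t[-1]), 1.0)
    taus = np.geomspace(max(t_span / 300.0, 2e-3), t_span, n_starts)
    lo = [0.0, _A_BOUNDS[0], _TAU_BOUNDS[0], _A_BOUNDS[0], _TAU_BOUNDS[0]]
    hi = [1.2, _A_BOUNDS[1], _TAU_BOUNDS[1], _A_BOUNDS[1], _TAU_BOUNDS[1]]

    best = None
    for i, tau1 in enumerate(taus):
        tau2 = min(tau1 * 10.0, _TAU_BOUNDS[1])
        x0 = [np.clip(f0_init, 0, 1.2), 0.6 * amp, tau1, 0.4 * amp, tau2]
        try:
            res = least_squares(
                lambda th: _double_exp(th, t) - y, x0, bounds=(lo, hi), method="trf"
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        if res.success and (best is None or rss < best[1]):
            best = (res.x, rss)

    degraded = False
    if best is None:
        # single-exponential fallback, reported as a degenerate double fit
        def single(th):
            f0, a, tau = th
            return f0 + a * (1.0 - np.exp(-t / tau)) - y

        res = least_squares(
            single,
            [np.clip(f0_init, 0, 1.2), amp, t_span / 3.0],
            bounds=([0, 0, _TAU_BOUNDS[0]], [1.2, 1.5, _TAU_BOUNDS[1]]),
        )
        f0, a, tau = res.x
        theta = np.array([f0, a, tau, 0.0, tau])
        rss = float(np.sum(res.fun**2))
        degraded = True
    else:
        theta, rss = best

    f0, a1, tau1, a2, tau2 = theta
    if tau1 > tau2:  # ordering convention: fast term first
        a1, a2, tau1, tau2 = a2, a1, tau2, tau1
    plateau = f0 + a1 + a2
    denom = 1.0 - f0
    mobile = (plateau - f0) / denom if denom > 1e-9 else float("nan")
    if np.isfinite(mobile):
        mobile = float(np.clip(mobile, 0.0, 1.05))

    def _rec(ts: float) -> float:
        try:
            return recovery_at(curve, ts)
        except ValueError:
            return float("nan")

    return FrapFit(
        f0=float(f0),
        a1=float(a1),
        tau1=float(tau1),
        a2=float(a2),
        tau2=float(tau2),
        mobile_fraction=float(mobile),
        recovery_5s=_rec(5.0),
        recovery_100s=_rec(100.0),
        fit_rss=rss,
        degraded=degraded,
    )


def recovery_at(curve: FrapCurve, t: float) -> float:
    """Fractional recovery at bleach-relative time ``t``.

    Linear interpolation of the relative-fluorescence curve, rescaled to
    ``(value - post-bleach minimum) / (1 - post-bleach minimum)`` so that
    constructs with different bleach depths are comparable.
    """
    pt = curve.post_times
    if t < pt[0] or t > pt[-1]:
        raise ValueError(f"t={t} s outside the sampled post-bleach range [{pt[0]}, {pt[-1]}]")
    val = float(np.interp(t, pt, curve.post_values))
    fmin = float(curve.post_values.min())
    denom = 1.0 - fmin
    if denom <= 1e-12:
        return 0.0
    return (val - fmin) / denom


# ---------------------------------------------------------------------------
# kymograph
# ---------------------------------------------------------------------------

def kymograph(
    frames: list[ImagingField],
    line: tuple[tuple[float, float], tuple[float, float]],
    width: int = 1,
) -> np.ndarray:
    """Position x time intensity matrix along a pixel segment.

    Each column is the ``width``-averaged intensity profile along ``line``
    (``((r0, c0), (r1, c1))``) in one frame, including pre-bleach frames.
    """
    (r0, c0), (r1, c1) = line
    if (r0, c0) == (r1, c1):
        raise ValueError("zero-length kymograph line")
    h, w = frames[0].data.shape
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError("kymograph line endpoint outside image bounds")
    cols = [
        profile_line(f.data, (r0, c0), (r1, c1), linewidth=width, mode="constant")
        for f in frames
    ]
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# inverse FRAP
# ---------------------------------------------------------------------------

def ifrap_efflux(
    curve: FrapCurve,
    window: float,
    internal_equilibration: float | None = None,
) -> IFrapResult:
    """Apparent efflux rate from an inverse-FRAP intensity-loss curve.

    Fits an ordinary least-squares line to percent intensity versus minutes
    over the post-bleach ``window`` (seconds); ``efflux_rate`` is the negated
    slope in %/min.  ``turnover_time`` extrapolates to complete loss
    (100/rate) in hours.  If ``internal_equilibration`` (seconds) is given,
    ``equilibration_ratio = turnover_time_s / internal_equilibration``.
    """
    if window > curve.post_times[-1] + 1e-9:
        raise ValueError("window exceeds the recorded post-bleach duration")
    sel = curve.post_times <= window + 1e-9
    t_min = curve.post_times[sel] / 60.0
    pct = 100.0 * curve.post_values[sel]
    if t_min.size < 2:
        raise ValueError("need at least two frames inside the window")
    flags: list[str] = []
    if np.allclose(pct, pct[0]):
        rate = 0.0
    else:
        fit = linregress(t_min, pct)
        rate = -float(fit.slope)
        if rate < 0:
            warnings.warn("positive slope (apparent influx); efflux rate set to 0")
            flags.append("apparent_influx")
            rate = 0.0
    if rate > 0:
        turnover_h = 100.0 / rate / 60.0
    else:
        turnover_h = float("nan")
        flags.append("no_efflux")
    ratio = float("nan")
    internal = float("nan") if internal_equilibration is None else float(internal_equilibration)
    if internal_equilibration is not None and np.isfinite(turnover_h):
        ratio = turnover_h * 3600.0 / internal
    return IFrapResult(
        efflux_rate=rate,
        turnover_time=turnover_h,
        equilibration_ratio=ratio,
        internal_equilibration_time=internal,
        flags=tuple(flags),
    )


def internal_equilibration_time(curve: FrapCurve, threshold: float = 0.95) -> float:
    """First time (s, bleach-relative) at which fractional recovery exceeds
    ``threshold`` of its fitted plateau.

    The plateau comes from the double-exponential fit; crossing time is
    linearly interpolated between frames.  Raises if the record never
    reaches the threshold, reporting the longest observed fraction.
    """
    fit = fit_double_exponential(curve)
    t = curve.post_times
    y = curve.post_values
    f0 = min(fit.f0, float(y.min()))
    denom = fit.plateau - f0
    if denom <= 1e-12:
        return float(t[0])  # flat curve: already at plateau
    frac = (y - f0) / denom
    above = np.nonzero(frac >= threshold)[0]
    if above.size == 0:
        raise ValueError(
            f"plateau never reached within record (max fraction {frac.max():.3f} "
            f"< threshold {threshold})"
        )
    i = int(above[0])
    if i == 0:
        return float(t[0])
    # interpolate the crossing between frames i-1 and i
    f_lo, f_hi = frac[i - 1], frac[i]
    w = (threshold - f_lo) / (f_hi - f_lo)
    return float(t[i - 1] + w * (t[i] - t[i - 1]))
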