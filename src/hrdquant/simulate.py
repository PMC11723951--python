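"""Synthetic nucleus images and reaction-diffusion-binding kinetics.

This module generates every input the downstream analysis stages consume,
with known ground truth:

* single-frame two-channel nucleus images (protein + DNA counterstain) in
  which bright chromocenter foci sit on a dimmer nucleoplasm, with optional
  Poisson + Gaussian read-out noise (:func:`make_nucleus_field`);
* photobleaching time series (FRAP and inverse FRAP) produced by a
  deterministic continuum two-field (free, bound) finite-difference scheme
  on a 2D lattice (:func:`simulate_frap`, :func:`simulate_ifrap`);
* expression series with a finite number of binding sites, so that
  chromocenter partitioning saturates as copy number exceeds site number
  (:func:`make_expression_series`).

Model
-----
Unbound molecules diffuse freely within the nucleus (coefficient ``D_free``,
reflecting boundary).  Binding sites are laid out as a top-hat density map,
high inside chromocenters and zero (or low) outside; there is no membrane or
potential barrier at the compartment boundary.  Mass-action binding to the
finite site pool,

    d(bound)/dt = k_on * free * (sites - bound) - k_off * bound,

retards exchange with the nucleoplasm and produces a steady-state partition
coefficient above 1 wherever sites are dense.  Bound molecules may in
addition hop between adjacent occupied-site lattice positions with a small
coefficient ``D_bound`` confined to the contiguous site region.  This direct
site-to-site transfer (facilitated dissociation / intersegment hopping) is
what lets a compartment mix internally on a timescale orders of magnitude
faster than it exchanges with the nucleoplasm: escape still requires a true
unbinding event at the slow ``k_off``.

Because free molecules equilibrate quickly across the nucleus, the full
steady state has a spatially uniform free concentration and a local bound
occupancy ``b = S * c / (c + Kd)`` with ``Kd = k_off / k_on``; the scalar
``c`` is obtained by mass balance (:func:`steady_state`).  Photobleaching
simulations start from this fixed point and evolve only the fluorescent
(free, bound) pair; the total occupancy field is stationary and enters the
fluorescent kinetics through the free-site map ``S - b``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

#: label values used in ground-truth / segmentation mask images
LABEL_BACKGROUND = 0
LABEL_NUCLEOPLASM = 1
LABEL_CHROMOCENTER = 2

PRESET_NAMES = ("retentive", "exchanging", "unbound")

# default chromocenter layout: (center_row, center_col, radius) in pixels,
# chosen to sit inside the default elliptical nucleus without touching
_DEFAULT_CHROMOCENTERS = (
    (20.0, 24.0, 6.0),
    (26.0, 44.0, 4.0),
    (40.0, 18.0, 4.0),
    (44.0, 38.0, 5.0),
    (31.0, 32.0, 3.5),
)


@dataclass(frozen=True)
class ImagingField:
    """One 2D fluorescence frame with physical metadata.

    Attributes
    ----------
    data:
        Intensity image in arbitrary units, shape ``(H, W)``.
    pixel_size:
        Pixel edge length in micrometres.
    time:
        Acquisition time in seconds (0 for single-frame fields).
    counterstain:
        Optional DNA counterstain channel (Hoechst/DAPI-like), same shape.
    """

    data: np.ndarray
    pixel_size: float
    time: float = 0.0
    counterstain: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GroundTruth:
    """Known truth attached to a synthetic field.

    ``labels`` assigns each pixel to background / nucleoplasm / chromocenter
    (mutually exclusive, jointly exhaustive); ``pc_true`` is the expected
    chromocenter/nucleoplasm concentration ratio of the noiseless signal and
    ``bound_fraction_true`` the fraction of molecules bound at steady state.
    """

    labels: np.ndarray
    pc_true: float
    bound_fraction_true: float = float("nan")


@dataclass(frozen=True)
class SimParams:
    """Full parameterization of the lattice reaction-diffusion-binding model.

    Units: lengths in pixels (with ``pixel_size`` um/px), rates in 1/s,
    diffusion in um^2/s, concentrations in molecules per pixel.
    """

    grid_shape: tuple[int, int] = (64, 64)
    pixel_size: float = 0.15
    nucleus_center: tuple[float, float] = (32.0, 32.0)
    nucleus_radii: tuple[float, float] = (21.0, 26.0)
    chromocenters: tuple[tuple[float, float, float], ...] = _DEFAULT_CHROMOCENTERS
    D_free: float = 1.0
    D_bound: float = 0.0
    k_on_per_site: float = 3.6e-5
    k_off: float = 1.2e-4
    site_density: float = 30.0
    site_density_out: float = 0.0
    n_molecules: float = 800.0
    bleach_depth: float = 0.0
    dt: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D_free < 0 or self.D_bound < 0:
            raise ValueError("diffusion coefficients must be non-negative")
        if self.k_off <= 0:
            raise ValueError("k_off must be positive")
        if self.k_on_per_site < 0:
            raise ValueError("k_on_per_site must be non-negative")
        if self.site_density < 0 or self.site_density_out < 0:
            raise ValueError("site densities must be non-negative")
        if not 0.0 <= self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in [0, 1]")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be positive")
        bound = self.stability_dt()
        if self.dt > bound * (1 + 1e-12):
            raise ValueError(
                f"dt={self.dt} violates the explicit-scheme stability bound "
                f"dt <= pixel_size^2/(4*D) = {bound:.6g} s"
            )

    def stability_dt(self) -> float:
        """Largest stable explicit-Euler step, ``px^2 / (4 * max(D))``."""
        d = max(self.D_free, self.D_bound, 1e-300)
        return self.pixel_size**2 / (4.0 * d)

    # --- geometry -------------------------------------------------------

    def nucleus_mask(self) -> np.ndarray:
        h, w = self.grid_shape
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = self.nucleus_center
        ry, rx = self.nucleus_radii
        return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    def chromocenter_mask(self) -> np.ndarray:
        h, w = self.grid_shape
        yy, xx = np.mgrid[0:h, 0:w]
        mask = np.zeros((h, w), dtype=bool)
        for cy, cx, r in self.chromocenters:
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        return mask & self.nucleus_mask()

    def labels(self) -> np.ndarray:
        nuc = self.nucleus_mask()
        cc = self.chromocenter_mask()
        lab = np.full(self.grid_shape, LABEL_BACKGROUND, dtype=np.uint8)
        lab[nuc] = LABEL_NUCLEOPLASM
        lab[cc] = LABEL_CHROMOCENTER
        return lab

    def site_map(self) -> np.ndarray:
        """Binding sites per pixel; zero outside the nucleus."""
        s = np.zeros(self.grid_shape, dtype=float)
        nuc = self.nucleus_mask()
        s[nuc] = self.site_density_out
        s[self.chromocenter_mask()] = self.site_density
        s[~nuc] = 0.0
        return s

    def total_sites(self) -> float:
        return float(self.site_map().sum())


def preset(name: str, **overrides) -> SimParams:
    """Return the :class:`SimParams` for a named kinetic phenotype.

    ``"retentive"`` -- dense chromocenter sites, slow unbinding
    (k_off = 1.2e-4/s, i.e. a maximal unbinding-limited efflux of
    ~0.7 %/min) and on-lattice bound hopping (D_bound = 0.025 um^2/s, so a
    half-bleached 0.9-um focus remixes to ~95% of plateau in ~30 s): fast
    internal mixing, minimal nucleoplasmic exchange, PC ~ 10.

    ``"exchanging"`` -- fast unbinding (k_off = 0.35/s): chromocenters
    still enriched (PC ~ 4) but whole-focus bleaches recover within tens of
    seconds through exchange with the nucleoplasm.

    ``"unbound"`` -- no binding sites: uniform nuclear distribution
    (PC ~ 1), recovery limited only by free diffusion.
    """
    presets = {
        "retentive": dict(
            D_free=1.0,
            D_bound=0.025,
            k_on_per_site=3.6e-5,
            k_off=1.2e-4,
            site_density=30.0,
            n_molecules=800.0,
        ),
        "exchanging": dict(
            D_free=1.0,
            D_bound=0.0,
            k_on_per_site=0.035,
            k_off=0.35,
            site_density=30.0,
            n_molecules=800.0,
        ),
        "unbound": dict(
            D_free=1.0,
            D_bound=0.0,
            k_on_per_site=0.0,
            k_off=1.0,
            site_density=0.0,
            n_molecules=800.0,
        ),
    }
    if name not in presets:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        )
    kw = presets[name]
    kw.update(overrides)
    return SimParams(**kw)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def steady_state(params: SimParams, n_molecules: float | None = None):
    """Analytic steady state of the binding model.

    Returns ``(c_free, bound_map)``: the uniform free concentration
    (molecules/px) and the per-pixel bound concentration.  Solves the mass
    balance ``c*A + sum(S*c/(c+Kd)) = N`` for ``c`` (monotone in ``c``, so a
    bracketing root find is exact to solver tolerance).
    """
    n = params.n_molecules if n_molecules is None else float(n_molecules)
    nuc = params.nucleus_mask()
    area = float(nuc.sum())
    smap = params.site_map()
    if params.k_on_per_site == 0.0 or smap.max() == 0.0:
        c = n / area
        return c, np.zeros_like(smap)
    kd = params.k_off / params.k_on_per_site
    s_sum = smap.sum()

    def balance(c):
        return c * area + s_sum_frac(c) - n

    def s_sum_frac(c):
        return float((smap * (c / (c + kd))).sum())

    hi = n / area
    lo = min(1e-12, hi * 1e-12)
    c = brentq(balance, lo, hi, xtol=1e-14, rtol=1e-14)
    bound = smap * (c / (c + kd))
    return float(c), bound


def _ground_truth(params: SimParams, c: float, bound: np.ndarray) -> GroundTruth:
    cc = params.chromocenter_mask()
    npl = params.nucleus_mask() & ~cc
    conc_cc = c + float(bound[cc].mean()) if cc.any() else float("nan")
    conc_np = c + float(bound[npl].mean())
    pc = conc_cc / conc_np if cc.any() else 1.0
    total = c * params.nucleus_mask().sum() + bound.sum()
    return GroundTruth(
        labels=params.labels(),
        pc_true=float(pc),
        bound_fraction_true=float(bound.sum() / total),
    )


# ---------------------------------------------------------------------------
# static image synthesis
# ---------------------------------------------------------------------------

def make_nucleus_field(
    params: SimParams,
    pc_target: float,
    mean_nuclear_intensity: float = 120.0,
    background_level: float = 10.0,
    noise: str = "none",
    read_noise_sd: float = 0.0,
    counterstain_levels: tuple[float, float] = (40.0, 160.0),
    rng: np.random.Generator | None = None,
) -> tuple[ImagingField, GroundTruth]:
    """Render a two-channel nucleus image with a prescribed partition coefficient.

    The noiseless protein channel satisfies exactly
    ``(cc - bg) / (np - bg) = pc_target`` where cc/np/bg are the mean
    chromocenter, nucleoplasm and background intensities.  The counterstain
    channel marks chromocenters at fixed contrast, independent of
    ``pc_target``.  ``noise="poisson"`` treats intensities as photon counts
    and adds shot noise plus optional Gaussian read noise.
    """
    if pc_target < 0:
        raise ValueError("pc_target must be non-negative")
    if mean_nuclear_intensity <= background_level:
        raise ValueError(
            "mean nuclear intensity must exceed the background level; the "
            "partition ratio is undefined with zero nucleoplasm signal"
        )
    lab = params.labels()
    nuc = lab != LABEL_BACKGROUND
    cc = lab == LABEL_CHROMOCENTER
    f_cc = cc.sum() / nuc.sum()
    # nucleoplasm signal s solves mean = bg + s*(1-f) + pc*s*f
    s = (mean_nuclear_intensity - background_level) / (1.0 - f_cc + pc_target * f_cc)
    if s <= 0:
        raise ValueError("requested intensities yield non-positive nucleoplasm signal")
    img = np.full(params.grid_shape, background_level, dtype=float)
    img[nuc] += s
    img[cc] += (pc_target - 1.0) * s

    d_np, d_cc = counterstain_levels
    dna = np.full(params.grid_shape, background_level, dtype=float)
    dna[nuc] += d_np
    dna[cc] += d_cc - d_np

    if noise == "poisson":
        rng = np.random.default_rng(params.seed) if rng is None else rng
        img = rng.poisson(img).astype(float)
        dna = rng.poisson(dna).astype(float)
        if read_noise_sd > 0:
            img += rng.normal(0.0, read_noise_sd, img.shape)
            dna += rng.normal(0.0, read_noise_sd, dna.shape)
    elif noise != "none":
        raise ValueError(f"unknown noise mode {noise!r}")

    fld = ImagingField(
        data=img,
        pixel_size=params.pixel_size,
        counterstain=dna,
        meta={"pc_target": pc_target, "noise": noise},
    )
    gt = GroundTruth(labels=lab, pc_true=float(pc_target))
    return fld, gt


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

_SHIFTS = ((0, 1), (0, -1), (1, 1), (1, -1))


def _neighbor_pairs(mask: np.ndarray):
    """Precompute, per shift, the boolean map of valid (in-mask) neighbor links."""
    pairs = []
    for axis, shift in _SHIFTS:
        nbm = np.roll(mask, shift, axis=axis)
        pairs.append((axis, shift, mask & nbm))
    return pairs


def _masked_laplacian(c: np.ndarray, pairs) -> np.ndarray:
    """Flux-form 4-neighbor Laplacian with reflecting walls at the mask edge.

    Fluxes are antisymmetric between neighbor pairs, so total mass is
    conserved to floating-point rounding at every step.
    """
    out = np.zeros_like(c)
    for axis, shift, link in pairs:
        out += np.where(link, np.roll(c, shift, axis=axis) - c, 0.0)
    return out


class _Kinetics:
    """Explicit integrator for the fluorescent (free, bound) pair."""

    def __init__(self, params: SimParams):
        self.p = params
        self.nuc = params.nucleus_mask()
        self.smap = params.site_map()
        self.c0, self.b0 = steady_state(params)
        self.site_region = self.smap > 0
        self.free_pairs = _neighbor_pairs(self.nuc)
        self.bound_pairs = _neighbor_pairs(self.site_region) if self.site_region.any() else None
        # free sites are constant because total occupancy is stationary
        self.s_free = self.smap - self.b0
        self.free = np.where(self.nuc, self.c0, 0.0)
        self.bound = self.b0.copy()
        px2 = params.pixel_size**2
        self.alpha_free = params.D_free * params.dt / px2
        self.alpha_bound = params.D_bound * params.dt / px2
        r_max = params.dt * (params.k_on_per_site * max(self.s_free.max(), 0.0) + params.k_off)
        if r_max >= 0.5:
            raise ValueError(
                f"dt={params.dt} too large for reaction rates (dt*(k_on*S+k_off)="
                f"{r_max:.3g} >= 0.5)"
            )

    def verify_stationary(self, n_steps: int = 5, tol: float = 1e-6) -> float:
        """Evolve a copy of the total fields briefly; return max relative drift."""
        f = np.where(self.nuc, self.c0, 0.0)
        b = self.b0.copy()
        p = self.p
        for _ in range(n_steps):
            react = p.dt * (p.k_on_per_site * f * (self.smap - b) - p.k_off * b)
            f2 = f + self.alpha_free * _masked_laplacian(f, self.free_pairs) - react
            b2 = b + react
            if self.bound_pairs is not None and self.alpha_bound > 0:
                b2 += self.alpha_bound * _masked_laplacian(b, self.bound_pairs)
            f, b = f2, b2
        scale = max(self.c0, float(self.b0.max()), 1e-300)
        drift = max(
            float(np.abs(f - np.where(self.nuc, self.c0, 0.0)).max()),
            float(np.abs(b - self.b0).max()),
        )
        return drift / scale

    def step(self, n: int = 1) -> None:
        p = self.p
        for _ in range(n):
            react = p.dt * (p.k_on_per_site * self.free * self.s_free - p.k_off * self.bound)
            f2 = self.free + self.alpha_free * _masked_laplacian(self.free, self.free_pairs) - react
            b2 = self.bound + react
            if self.bound_pairs is not None and self.alpha_bound > 0:
                b2 += self.alpha_bound * _masked_laplacian(self.bound, self.bound_pairs)
            self.free, self.bound = f2, b2

    def bleach(self, roi: np.ndarray, depth: float) -> None:
        self.free = np.where(roi, self.free * depth, self.free)
        self.bound = np.where(roi, self.bound * depth, self.bound)

    def fluorescence(self) -> np.ndarray:
        return self.free + self.bound

    def total_fluorescent(self) -> float:
        return float(self.free.sum() + self.bound.sum())


# lightweight record handed to the frap_quant module; defined here because the
# simulator writes it, but the analysis module re-exports it as its own type
@dataclass
class FrapSeries:
    """Per-frame mean ROI intensities for one photobleaching experiment.

    ``traces`` maps ROI roles (``"bleach"``, ``"nucleus"``, ``"background"``)
    to per-frame mean intensities; ``bleach_index`` is the index of the first
    post-bleach frame; ``roi_kind`` is one of ``{"total", "partial",
    "inverse"}``.
    """

    times: np.ndarray
    traces: dict[str, np.ndarray]
    bleach_index: int
    roi_kind: str = "total"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.traces = {k: np.asarray(v, dtype=float) for k, v in self.traces.items()}
        if self.bleach_index < 1:
            raise ValueError("at least one frame must precede the bleach")
        for k, v in self.traces.items():
            if v.shape != self.times.shape:
                raise ValueError(f"trace {k!r} length does not match times")

    def copy(self) -> "FrapSeries":
        return FrapSeries(
            times=self.times.copy(),
            traces={k: v.copy() for k, v in self.traces.items()},
            bleach_index=self.bleach_index,
            roi_kind=self.roi_kind,
            meta=dict(self.meta),
        )


def simulate_frap(
    params: SimParams,
    bleach_roi: np.ndarray,
    t_end: float,
    frame_interval: float,
    n_prebleach: int = 2,
    roi_kind: str = "total",
    measure_roi: np.ndarray | None = None,
    intensity_gain: float = 200.0,
    offset: float = 0.0,
    acq_bleach_per_frame: float = 0.0,
    noise: str = "none",
    rng: np.random.Generator | None = None,
    record_frames: bool = True,
    stationarity_tol: float = 1e-6,
) -> tuple[list[ImagingField], FrapSeries]:
    """Simulate a photobleaching experiment and return frames plus ROI traces.

    The system starts at the analytic steady state (verified stationary to
    ``stationarity_tol``), records ``n_prebleach`` frames, instantaneously
    multiplies both fluorescent fields by ``params.bleach_depth`` inside
    ``bleach_roi``, then evolves to ``t_end`` past the bleach.  Fluorescent
    mass is conserved at every step except the bleach event (per-frame totals
    in ``series.meta["fluorescent_mass"]``).

    ``measure_roi`` defaults to ``bleach_roi``; for inverse FRAP pass the
    spared region as ``measure_roi`` and the complement as ``bleach_roi``.
    ``acq_bleach_per_frame`` multiplies the fields by ``1 - rate`` at each
    acquisition to emulate scanning photobleaching.
    """
    if bleach_roi.shape != tuple(params.grid_shape):
        raise ValueError("bleach_roi shape does not match the grid")
    if n_prebleach < 1:
        raise ValueError("need at least one pre-bleach frame")
    # refine the step so an integer number of sub-steps tiles each frame
    n_sub = max(1, math.ceil(frame_interval / params.dt))
    dt_eff = frame_interval / n_sub
    if dt_eff < params.dt:
        params = dataclasses.replace(params, dt=dt_eff)
    kin = _Kinetics(params)
    drift = kin.verify_stationary(tol=stationarity_tol)
    if drift > stationarity_tol:
        raise RuntimeError(
            f"steady state not stationary (relative drift {drift:.2e} > {stationarity_tol})"
        )
    roi = np.asarray(bleach_roi, dtype=bool)
    meas = roi if measure_roi is None else np.asarray(measure_roi, dtype=bool)
    lab = params.labels()
    nuc_mask = lab != LABEL_BACKGROUND
    bg_mask = ~nuc_mask

    n_post = int(round(t_end / frame_interval))
    times, frames = [], []
    rois = {"bleach": [], "nucleus": [], "background": []}
    mass = []
    if noise == "poisson" and rng is None:
        rng = np.random.default_rng(params.seed)

    def acquire(t: float) -> None:
        if acq_bleach_per_frame > 0:
            kin.free *= 1.0 - acq_bleach_per_frame
            kin.bound *= 1.0 - acq_bleach_per_frame
        img = intensity_gain * kin.fluorescence() + offset
        if noise == "poisson":
            img = rng.poisson(np.maximum(img, 0.0)).astype(float)
        times.append(t)
        rois["bleach"].append(float(img[meas].mean()))
        rois["nucleus"].append(float(img[nuc_mask].mean()))
        rois["background"].append(float(img[bg_mask].mean()))
        mass.append(kin.total_fluorescent())
        if record_frames:
            frames.append(
                ImagingField(data=img, pixel_size=params.pixel_size, time=t)
            )

    for i in range(n_prebleach):
        acquire((i - n_prebleach) * frame_interval)
        if i < n_prebleach - 1:
            kin.step(n_sub)
    kin.bleach(roi, params.bleach_depth)
    acquire(0.0)
    for j in range(1, n_post + 1):
        kin.step(n_sub)
        acquire(j * frame_interval)

    series = FrapSeries(
        times=np.array(times),
        traces={k: np.array(v) for k, v in rois.items()},
        bleach_index=n_prebleach,
        roi_kind=roi_kind,
        meta={
            "fluorescent_mass": np.array(mass),
            "ground_truth_pc": _ground_truth(params, kin.c0, kin.b0).pc_true,
            "frame_interval": frame_interval,
            "n_substeps": n_sub,
        },
    )
    return frames, series


def chromocenter_roi(params: SimParams, index: int = 0, half: bool = False) -> np.ndarray:
    """Mask of one chromocenter; ``half=True`` keeps only its left half
    (for partial-bleach experiments)."""
    cy, cx, r = params.chromocenters[index]
    h, w = params.grid_shape
    yy, xx = np.mgrid[0:h, 0:w]
    roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    if half:
        roi &= xx <= cx
    return roi & params.nucleus_mask()


def simulate_ifrap(
    params: SimParams,
    spared_index: int = 0,
    t_end: float = 300.0,
    frame_interval: float = 5.0,
    **kwargs,
) -> tuple[list[ImagingField], FrapSeries]:
    """Inverse FRAP: bleach the whole nucleus except one chromocenter and
    follow the spared focus' intensity loss."""
    spared = chromocenter_roi(params, spared_index)
    bleach = params.nucleus_mask() & ~spared
    return simulate_frap(
        params,
        bleach,
        t_end,
        frame_interval,
        roi_kind="inverse",
        measure_roi=spared,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# expression series
# ---------------------------------------------------------------------------

def make_expression_series(
    params: SimParams,
    copy_numbers: Sequence[float],
    seed: int | None = None,
    intensity_gain: float = 0.5,
    background_level: float = 10.0,
    noise: str = "none",
) -> list[tuple[ImagingField, GroundTruth]]:
    """Render steady-state nucleus images over a range of expression levels.

    With a finite binding-site pool, chromocenter concentration rises
    sub-linearly once copies exceed sites and the partition coefficient
    falls toward a plateau just above 1.  ``intensity_gain`` converts
    molecules/px to arbitrary intensity units (kept small so Poisson noise
    at high copy numbers stays proportional).
    """
    copy_numbers = list(copy_numbers)
    if any(n <= 0 for n in copy_numbers):
        raise ValueError("copy numbers must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    out = []
    for n in copy_numbers:
        c, bound = steady_state(params, n)
        conc = np.where(params.nucleus_mask(), c, 0.0) + bound
        img = intensity_gain * conc + background_level
        dna = np.full(params.grid_shape, background_level, dtype=float)
        dna[params.nucleus_mask()] += 40.0
        dna[params.chromocenter_mask()] += 120.0
        if noise == "poisson":
            img = rng.poisson(img).astype(float)
            dna = rng.poisson(dna).astype(float)
        gt = _ground_truth(params, c, bound)
        fld = ImagingField(
            data=img,
            pixel_size=params.pixel_size,
            counterstain=dna,
            meta={"copy_number": float(n), "free_conc": c},
        )
        out.append((fld, gt))
    return out
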