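"""Digital renography phantom.

Generates paired synthetic dynamic studies — a contrast-enhanced MR
urography (fMRU) signal series and a posterior-projection renal
scintigraphy (DRS) count series — from a single :class:`PhantomSpec` with
known ground truth, emulating the statistical structure the analysis
pipeline assumes:

* an aortic input function shaped as a gamma-variate first pass (the
  micro-bolus) plus an exponential-tail recirculation plateau;
* renal parenchymal enhancement following the irreversible-uptake
  (Rutland-Patlak) model ``Q(t) = K·∫P dτ + V_b·P(t)``, with tracer
  handed to the collecting system after a parenchymal transit time;
* a collecting-system (pelvis) compartment draining at a per-pattern
  outflow rate ``k_out``: fast (normal decline), inflow-balancing
  (borderline plateau) or zero (ever-increasing accumulation);
* the dual temporal resolution of the fMRU protocol (one 5 s frame for
  the first 5 min, then 30 s frames for 5 min);
* Gaussian signal noise for MR, Poisson count noise for scintigraphy,
  with a C-shaped perirenal background region on the planar view.

Geometry is deliberately schematic: axis-aligned ellipsoidal kidneys with
a small medial pelvis ellipsoid, a vertical aortic cylinder, a cardiac
blood-pool disc on the planar view. Index convention: the x axis increases
toward the patient's left, so the left kidney sits at larger x.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Literal

import numpy as np
from scipy.special import gammainc

from .curves import RegionMask, TimeActivityCurve
from .exceptions import ConfigurationError, InputError, ParameterError

__all__ = [
    "AcquisitionSchedule",
    "PhantomSpec",
    "PhantomTruth",
    "MRUStudy",
    "DRSStudy",
    "aortic_input",
    "renal_curve",
    "simulate_mru",
    "simulate_drs",
    "simulate_study",
    "parenchymal_peak",
]

Pattern = Literal["normal", "borderline", "accumulation"]
PATTERNS: tuple[str, ...] = ("normal", "borderline", "accumulation")

#: integration step (s) of the internal dense grid used by the forward model
_DENSE_DT = 2.5


@dataclass
class AcquisitionSchedule:
    """Frame timing of a dynamic acquisition.

    Frames must be non-overlapping with positive durations. The default
    fMRU schedule is 60 frames of 5 s followed by 10 frames of 30 s
    (10 min total); the default DRS schedule is 120 frames of 10 s
    (20 min, a typical MAG3 acquisition).
    """

    frame_start_times: np.ndarray
    frame_durations: np.ndarray
    modality: Literal["mru", "drs"] = "mru"

    def __post_init__(self) -> None:
        self.frame_start_times = np.asarray(self.frame_start_times, dtype=float)
        self.frame_durations = np.asarray(self.frame_durations, dtype=float)
        if self.frame_start_times.ndim != 1 or len(self.frame_start_times) == 0:
            raise InputError("schedule must contain at least one frame")
        if len(self.frame_start_times) != len(self.frame_durations):
            raise InputError("frame start times and durations differ in length")
        if np.any(self.frame_durations <= 0):
            raise InputError("frame durations must be positive")
        ends = self.frame_start_times + self.frame_durations
        if np.any(self.frame_start_times[1:] - ends[:-1] < -1e-9):
            raise InputError("frames must be non-overlapping and ordered")
        if self.modality not in ("mru", "drs"):
            raise InputError("modality must be 'mru' or 'drs'")

    @property
    def n_frames(self) -> int:
        return len(self.frame_start_times)

    @property
    def midpoints(self) -> np.ndarray:
        return self.frame_start_times + self.frame_durations / 2.0

    @property
    def end_time(self) -> float:
        return float(self.frame_start_times[-1] + self.frame_durations[-1])

    @classmethod
    def mru_default(cls) -> "AcquisitionSchedule":
        starts = np.concatenate([5.0 * np.arange(60), 300.0 + 30.0 * np.arange(10)])
        durs = np.concatenate([np.full(60, 5.0), np.full(10, 30.0)])
        return cls(starts, durs, "mru")

    @classmethod
    def drs_default(cls) -> "AcquisitionSchedule":
        return cls(10.0 * np.arange(120), np.full(120, 10.0), "drs")


def _gamma_variate(t: np.ndarray, t0: float, alpha: float, beta: float,
                   amplitude: float) -> np.ndarray:
    """First-pass bolus, normalized so the maximum equals ``amplitude``."""
    u = np.clip((np.asarray(t, dtype=float) - t0) / beta, 0.0, None)
    with np.errstate(invalid="ignore"):
        out = amplitude * (u / alpha) ** alpha * np.exp(alpha - u)
    return np.where(u > 0, out, 0.0)


def _aortic_values(t: np.ndarray, peak_time: float, shape_alpha: float,
                   scale_beta: float, recirculation_fraction: float,
                   amplitude: float) -> np.ndarray:
    """Aortic input evaluated on an arbitrary time grid.

    First pass ``A·(t−t0)^α·exp(−(t−t0)/β)`` (zero before bolus arrival
    ``t0 = peak_time − α·β``) plus a recirculation term rising to a plateau
    of ``recirculation_fraction × amplitude``: the first pass convolved
    with a unit-step tail, which has the closed form of the regularized
    lower incomplete gamma function.
    """
    t0 = peak_time - shape_alpha * scale_beta
    g = _gamma_variate(t, t0, shape_alpha, scale_beta, amplitude)
    u = np.clip((np.asarray(t, dtype=float) - t0) / scale_beta, 0.0, None)
    recirc = recirculation_fraction * amplitude * gammainc(shape_alpha + 1.0, u)
    return g + recirc


def aortic_input(schedule: AcquisitionSchedule, peak_time: float = 40.0,
                 shape_alpha: float = 2.5, scale_beta: float = 12.0,
                 recirculation_fraction: float = 0.1,
                 amplitude: float = 1.0) -> TimeActivityCurve:
    """Noise-free aortic input function sampled at frame midpoints.

    Parameters
    ----------
    peak_time
        Time (s) of the first-pass maximum; bolus arrival is at
        ``peak_time − shape_alpha·scale_beta``.
    shape_alpha, scale_beta
        Gamma-variate shape (dimensionless) and scale (s); both positive.
    recirculation_fraction
        Plateau level of the recirculation term as a fraction of the
        first-pass peak; 0 gives a pure gamma-variate.
    amplitude
        First-pass peak value (a.u.).
    """
    if shape_alpha <= 0 or scale_beta <= 0:
        raise ParameterError("shape_alpha and scale_beta must be positive")
    if not 0.0 <= recirculation_fraction < 1.0:
        raise ParameterError("recirculation_fraction must be in [0, 1)")
    if schedule.n_frames == 0:
        raise InputError("schedule is empty")
    if not (0.0 < peak_time < schedule.end_time):
        raise ParameterError("peak_time must lie within the acquisition span")
    values = _aortic_values(schedule.midpoints, peak_time, shape_alpha,
                            scale_beta, recirculation_fraction, amplitude)
    return TimeActivityCurve(
        times=schedule.midpoints, durations=schedule.frame_durations,
        values=values, region_label="aorta", modality=schedule.modality)


@dataclass
class PhantomSpec:
    """Ground-truth configuration of one paired phantom study.

    ``true_srf_left`` is not a free parameter: it is derived from volumes
    and uptake slopes as ``100·V_L·K_L/(V_L·K_L + V_R·K_R)`` so that the
    recorded truth is always consistent with the forward model. Use
    :meth:`from_srf` to build a spec targeting a given left SRF.
    """

    volume_left: float = 120.0          #: parenchymal volume, mL
    volume_right: float = 120.0
    patlak_slope_left: float = 0.004    #: uptake constant K, s^-1
    patlak_slope_right: float = 0.004
    blood_volume_fraction: float = 0.04  #: Patlak intercept term V_b
    drainage_pattern_left: str = "normal"
    drainage_pattern_right: str = "normal"
    outflow_rate_normal: float = 0.02        #: pelvis k_out, s^-1
    outflow_rate_borderline: float = 0.0024  #: balances inflow at plateau
    outflow_rate_accumulation: float = 0.0
    transit_time_s: float = 180.0       #: parenchyma-to-pelvis delay
    pelvis_volume_ml: float = 4.0
    aortic_peak_time: float = 40.0
    aortic_shape_alpha: float = 2.5
    aortic_scale_beta: float = 12.0
    recirculation_fraction: float = 0.1
    mru_noise_sd: float = 0.002         #: additive Gaussian signal sd, a.u.
    drs_count_scale: float = 10000.0    #: peak whole-kidney counts/frame
    background_level: float = 0.1       #: tissue activity / kidney peak
    seed: int = 0

    def __post_init__(self) -> None:
        if self.volume_left <= 0 or self.volume_right <= 0:
            raise ParameterError("kidney volumes must be positive")
        if self.patlak_slope_left < 0 or self.patlak_slope_right < 0:
            raise ParameterError("uptake slopes must be non-negative")
        if self.patlak_slope_left + self.patlak_slope_right == 0:
            raise ParameterError("at least one kidney must have K > 0")
        for name in ("outflow_rate_normal", "outflow_rate_borderline",
                     "outflow_rate_accumulation"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.outflow_rate_accumulation != 0.0:
            raise ParameterError(
                "the accumulation pattern is defined by zero outflow")
        for side in ("left", "right"):
            if getattr(self, f"drainage_pattern_{side}") not in PATTERNS:
                raise InputError(
                    f"drainage pattern must be one of {PATTERNS}")
        if self.mru_noise_sd < 0 or self.drs_count_scale <= 0:
            raise ParameterError("invalid noise configuration")
        if not 0 <= self.background_level < 1:
            raise ParameterError("background_level must be in [0, 1)")

    @property
    def true_srf_left(self) -> float:
        """Ground-truth volumetric left split renal function, percent."""
        fl = self.volume_left * self.patlak_slope_left
        fr = self.volume_right * self.patlak_slope_right
        return 100.0 * fl / (fl + fr)

    @property
    def true_srf_right(self) -> float:
        return 100.0 - self.true_srf_left

    def slope(self, side: str) -> float:
        if side not in ("left", "right"):
            raise InputError("side must be 'left' or 'right'")
        return getattr(self, f"patlak_slope_{side}")

    def pattern(self, side: str) -> str:
        if side not in ("left", "right"):
            raise InputError("side must be 'left' or 'right'")
        return getattr(self, f"drainage_pattern_{side}")

    def outflow_rate(self, pattern: str) -> float:
        if pattern not in PATTERNS:
            raise InputError(f"unknown drainage pattern {pattern!r}")
        return getattr(self, f"outflow_rate_{pattern}")

    def aortic_params(self) -> dict:
        return dict(peak_time=self.aortic_peak_time,
                    shape_alpha=self.aortic_shape_alpha,
                    scale_beta=self.aortic_scale_beta,
                    recirculation_fraction=self.recirculation_fraction,
                    amplitude=1.0)

    @classmethod
    def from_srf(cls, srf_left: float, volume_left: float = 120.0,
                 volume_right: float = 120.0, mean_slope: float = 0.004,
                 **kwargs) -> "PhantomSpec":
        """Build a spec whose true left SRF equals ``srf_left`` percent.

        The right slope is set to ``mean_slope`` and the left slope solved
        from the SRF identity given the requested volumes.
        """
        if not 0 < srf_left < 100:
            raise ParameterError("srf_left must be strictly between 0 and 100")
        k_right = mean_slope
        k_left = mean_slope * (srf_left / (100.0 - srf_left)) * (
            volume_right / volume_left)
        return cls(volume_left=volume_left, volume_right=volume_right,
                   patlak_slope_left=k_left, patlak_slope_right=k_right,
                   **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_srf_left"] = self.true_srf_left
        return d


@dataclass(frozen=True)
class PhantomTruth:
    """Immutable ground truth recorded before noise is applied."""

    srf_left: float
    srf_right: float
    volume_left: float
    volume_right: float
    pattern_left: str
    pattern_right: str
    seed: int

    @classmethod
    def from_spec(cls, spec: PhantomSpec) -> "PhantomTruth":
        return cls(srf_left=spec.true_srf_left, srf_right=spec.true_srf_right,
                   volume_left=spec.volume_left, volume_right=spec.volume_right,
                   pattern_left=spec.drainage_pattern_left,
                   pattern_right=spec.drainage_pattern_right, seed=spec.seed)

    def pattern(self, side: str) -> str:
        return getattr(self, f"pattern_{side}")


def _dense_grid(end_time: float) -> np.ndarray:
    return np.arange(0.0, end_time + _DENSE_DT, _DENSE_DT)


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid
    return cumulative_trapezoid(y, x, initial=0.0)


def _renal_components(spec: PhantomSpec, side: str,
                      input_curve: TimeActivityCurve,
                      schedule: AcquisitionSchedule):
    """Noise-free parenchymal (q) and pelvis (z) curves at frame midpoints.

    Both are expressed per unit parenchymal volume so the whole-kidney
    curve ``q + z`` is independent of kidney size. Internally the model
    runs on a dense uniform grid: the cumulative aortic integral gives the
    Patlak uptake, a pure delay moves tracer from parenchyma to pelvis
    after ``transit_time_s``, and the pelvis ODE ``z' = K·P(t−T) − k_out·z``
    is advanced with an exact exponential-integrator step.
    """
    K = spec.slope(side)
    k_out = spec.outflow_rate(spec.pattern(side))
    T = spec.transit_time_s
    vb = spec.blood_volume_fraction

    td = _dense_grid(schedule.end_time)
    p = np.interp(td, input_curve.times, input_curve.values,
                  left=float(input_curve.values[0]))
    C = _cumtrapz(p, td)
    C_delayed = np.interp(td - T, td, C, left=0.0)
    p_delayed = np.interp(td - T, td, p, left=0.0)

    q = K * (C - C_delayed) + vb * p

    z = np.zeros_like(td)
    dt = _DENSE_DT
    inflow_mid = K * np.interp(td[:-1] + dt / 2.0 - T, td, p, left=0.0)
    if k_out > 0:
        decay = np.exp(-k_out * dt)
        gain = (1.0 - decay) / k_out
        for i in range(len(td) - 1):
            z[i + 1] = z[i] * decay + inflow_mid[i] * gain
    else:
        z[1:] = np.cumsum(inflow_mid) * dt

    t = schedule.midpoints
    return np.interp(t, td, q), np.interp(t, td, z)


def renal_curve(spec: PhantomSpec, side: str, input_curve: TimeActivityCurve,
                schedule: AcquisitionSchedule | None = None) -> TimeActivityCurve:
    """Noise-free whole-kidney (parenchyma + collecting system) curve.

    Values are per unit parenchymal volume (a.u.): parenchymal uptake
    ``K·∫P + V_b·P`` feeding the pelvis compartment, whose outflow rate is
    set by the side's drainage pattern.
    """
    if side not in ("left", "right"):
        raise InputError("side must be 'left' or 'right'")
    if schedule is None:
        schedule = AcquisitionSchedule(
            input_curve.times - input_curve.durations / 2.0,
            input_curve.durations,
            input_curve.modality or "mru")
    if not np.allclose(schedule.midpoints, input_curve.times):
        raise InputError("input curve is not defined on the given schedule")
    q, z = _renal_components(spec, side, input_curve, schedule)
    return TimeActivityCurve(
        times=schedule.midpoints, durations=schedule.frame_durations,
        values=q + z, region_label=f"{side}_kidney",
        modality=schedule.modality)


def parenchymal_peak(spec: PhantomSpec,
                     schedule: AcquisitionSchedule | None = None) -> float:
    """Peak of the noise-free parenchymal signal (a.u.), larger kidney.

    Convenience for expressing MR noise as a fraction of the parenchymal
    peak (e.g. ``spec.mru_noise_sd = 0.01 * parenchymal_peak(spec)``).
    """
    schedule = schedule or AcquisitionSchedule.mru_default()
    aorta = aortic_input(schedule, **spec.aortic_params())
    peak = 0.0
    for side in ("left", "right"):
        q, _ = _renal_components(spec, side, aorta, schedule)
        peak = max(peak, float(q.max()))
    return peak


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

#: fixed kidney shape: cranio-caudal semi-axis is twice the transverse ones
_KIDNEY_ASPECT = 2.0
_KIDNEY_OFFSET_X = 55.0   # mm from midline
_AORTA_RADIUS = 6.0       # mm


def _semi_axes(volume_ml: float) -> tuple[float, float, float]:
    """Semi-axes (ax, ay, az) in mm of an ellipsoid of the given volume."""
    v_mm3 = volume_ml * 1000.0
    ax = (3.0 * v_mm3 / (4.0 * np.pi * _KIDNEY_ASPECT)) ** (1.0 / 3.0)
    return ax, ax, _KIDNEY_ASPECT * ax


def _ellipsoid_mask(xg, yg, zg, center, semi) -> np.ndarray:
    cx, cy, cz = center
    ax, ay, az = semi
    return (((xg - cx) / ax) ** 2 + ((yg - cy) / ay) ** 2
            + ((zg - cz) / az) ** 2) <= 1.0


@dataclass
class MRUStudy:
    """Synthetic dynamic MR urography study."""

    frames: np.ndarray               #: (n_frames, nx, ny, nz), a.u.
    schedule: AcquisitionSchedule
    voxel_size: tuple[float, float, float]  #: mm
    masks: dict[str, RegionMask]
    t2_volume: np.ndarray            #: (nx, ny, nz) static volumetric frame
    truth: PhantomTruth
    spec: PhantomSpec
    modality: str = "mru"

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return float(np.prod(self.voxel_size))


@dataclass
class DRSStudy:
    """Synthetic posterior-projection renal scintigraphy study."""

    frames: np.ndarray               #: (n_frames, nx, nz), counts/frame
    schedule: AcquisitionSchedule
    pixel_size: tuple[float, float]  #: mm
    masks: dict[str, RegionMask]
    truth: PhantomTruth
    spec: PhantomSpec
    modality: str = "drs"

    @property
    def pixel_area(self) -> float:
        """Pixel area in mm^2."""
        return float(np.prod(self.pixel_size))


def _mru_grid(voxel_size, shape):
    dx, dy, dz = voxel_size
    nx, ny, nz = shape
    x = (np.arange(nx) - nx / 2.0 + 0.5) * dx
    y = (np.arange(ny) - ny / 2.0 + 0.5) * dy
    z = (np.arange(nz) - nz / 2.0 + 0.5) * dz
    return np.meshgrid(x, y, z, indexing="ij")


def simulate_mru(spec: PhantomSpec,
                 schedule: AcquisitionSchedule | None = None,
                 voxel_size: tuple[float, float, float] = (2.0, 2.0, 4.0),
                 shape: tuple[int, int, int] = (96, 48, 40)) -> MRUStudy:
    """Simulate a 4D dynamic MR urography study.

    Two ellipsoidal parenchymal kidneys (volumes from the spec) with small
    medial pelvis ellipsoids, an aortic cylinder and a low-signal tissue
    bed are rendered on a labeled voxel grid; the parenchymal voxel signal
    is the Patlak forward model, the pelvis voxel signal the collecting
    system compartment scaled by the parenchyma-to-pelvis volume ratio.
    Additive Gaussian noise of sd ``spec.mru_noise_sd`` is applied to every
    voxel of every frame. A static T2-like volume (bright parenchyma) is
    returned for volumetric segmentation. Fully reproducible from the seed.
    """
    schedule = schedule or AcquisitionSchedule.mru_default()
    xg, yg, zg = _mru_grid(voxel_size, shape)
    extent_x = shape[0] * voxel_size[0] / 2.0
    extent_z = shape[2] * voxel_size[2] / 2.0

    masks_bool: dict[str, np.ndarray] = {}
    pel_semi = _semi_axes(spec.pelvis_volume_ml)
    for side, sign, vol in (("left", +1.0, spec.volume_left),
                            ("right", -1.0, spec.volume_right)):
        semi = _semi_axes(vol)
        if _KIDNEY_OFFSET_X + semi[0] > extent_x or semi[2] > extent_z:
            raise ConfigurationError(
                f"{side} kidney of {vol} mL does not fit on the voxel grid")
        center = (sign * _KIDNEY_OFFSET_X, 0.0, 0.0)
        kid = _ellipsoid_mask(xg, yg, zg, center, semi)
        pel_center = (sign * (_KIDNEY_OFFSET_X - semi[0] - pel_semi[0]), 0.0, 0.0)
        if abs(pel_center[0]) - pel_semi[0] < _AORTA_RADIUS:
            raise ConfigurationError("pelvis overlaps the aorta on this grid")
        pel = _ellipsoid_mask(xg, yg, zg, pel_center, pel_semi) & ~kid
        masks_bool[f"{side}_kidney"] = kid
        masks_bool[f"{side}_pelvis"] = pel
    aorta = (xg ** 2 + yg ** 2) <= _AORTA_RADIUS ** 2
    masks_bool["aorta"] = aorta
    background = (yg > 30.0) & (np.abs(xg) < 40.0) & (np.abs(zg) < 60.0)
    structures = (masks_bool["left_kidney"] | masks_bool["right_kidney"]
                  | masks_bool["left_pelvis"] | masks_bool["right_pelvis"]
                  | aorta)
    masks_bool["background"] = background & ~structures

    aorta_curve = aortic_input(schedule, **spec.aortic_params())
    p = aorta_curve.values
    tissue = 0.02 + 0.02 * gammainc(
        spec.aortic_shape_alpha + 1.0,
        np.clip((schedule.midpoints
                 - (spec.aortic_peak_time
                    - spec.aortic_shape_alpha * spec.aortic_scale_beta))
                / spec.aortic_scale_beta, 0.0, None))

    voxel_volume = float(np.prod(voxel_size))
    frames = np.empty((schedule.n_frames, *shape), dtype=np.float32)
    frames[:] = tissue[:, None, None, None].astype(np.float32)
    frames[:, aorta] = p[:, None].astype(np.float32)
    for side in ("left", "right"):
        q, z = _renal_components(spec, side, aorta_curve, schedule)
        kid = masks_bool[f"{side}_kidney"]
        pel = masks_bool[f"{side}_pelvis"]
        v_par = kid.sum() * voxel_volume
        v_pel = max(pel.sum(), 1) * voxel_volume
        frames[:, kid] = q[:, None].astype(np.float32)
        frames[:, pel] = (z * (v_par / v_pel))[:, None].astype(np.float32)

    truth = PhantomTruth.from_spec(spec)
    rng = np.random.default_rng([spec.seed, 0])
    if spec.mru_noise_sd > 0:
        frames += rng.standard_normal(frames.shape, dtype=np.float32) \
            * np.float32(spec.mru_noise_sd)

    t2 = np.full(shape, 0.05, dtype=np.float32)
    t2[masks_bool["left_kidney"] | masks_bool["right_kidney"]] = 1.0
    t2[masks_bool["left_pelvis"] | masks_bool["right_pelvis"]] = 0.3
    t2 += rng.standard_normal(shape, dtype=np.float32) * np.float32(0.02)

    masks = {}
    for side in ("left", "right"):
        masks[f"{side}_kidney"] = RegionMask(
            f"{side}_kidney", masks_bool[f"{side}_kidney"], voxel_volume)
        masks[f"{side}_whole"] = RegionMask(
            f"{side}_whole",
            masks_bool[f"{side}_kidney"] | masks_bool[f"{side}_pelvis"],
            voxel_volume)
    masks["aorta"] = RegionMask("aorta", masks_bool["aorta"], voxel_volume)
    masks["background"] = RegionMask("background", masks_bool["background"],
                                     voxel_volume)
    return MRUStudy(frames=frames, schedule=schedule, voxel_size=voxel_size,
                    masks=masks, t2_volume=t2, truth=truth, spec=spec)


def _ellipse_chord(xg, zg, center, semi_xz, semi_y) -> np.ndarray:
    """Path length (mm) through an ellipsoid along the projection axis."""
    cx, cz = center
    ax, az = semi_xz
    u2 = ((xg - cx) / ax) ** 2 + ((zg - cz) / az) ** 2
    return 2.0 * semi_y * np.sqrt(np.clip(1.0 - u2, 0.0, None))


def _c_shaped_background(xg, zg, center, semi_xz, sign) -> np.ndarray:
    """Perirenal annulus (1.15–1.6 × the kidney ellipse) open medially."""
    cx, cz = center
    ax, az = semi_xz
    u = np.sqrt(((xg - cx) / ax) ** 2 + ((zg - cz) / az) ** 2)
    annulus = (u >= 1.15) & (u <= 1.6)
    with np.errstate(invalid="ignore", divide="ignore"):
        medial_component = -sign * (xg - cx) / (ax * np.maximum(u, 1e-12))
    return annulus & (medial_component < 0.5)


def simulate_drs(spec: PhantomSpec,
                 schedule: AcquisitionSchedule | None = None,
                 pixel_size: tuple[float, float] = (4.0, 4.0),
                 shape: tuple[int, int] = (96, 96)) -> DRSStudy:
    """Simulate a posterior-projection dynamic scintigraphy study.

    Per-pixel expected counts are path-length integrals through the
    phantom (kidneys, pelves, cardiac blood pool, and a uniform body
    background whose level is ``spec.background_level`` of the peak
    parenchymal activity density, following the blood-pool time course),
    calibrated so the larger kidney's noise-free whole-kidney peak equals
    ``spec.drs_count_scale`` counts/frame, then Poisson-sampled.
    """
    schedule = schedule or AcquisitionSchedule.drs_default()
    nx, nz = shape
    dx, dz = pixel_size
    x = (np.arange(nx) - nx / 2.0 + 0.5) * dx
    z = (np.arange(nz) - nz / 2.0 + 0.5) * dz
    xg, zg = np.meshgrid(x, z, indexing="ij")
    pixel_area = dx * dz

    aorta_curve = aortic_input(schedule, **spec.aortic_params())
    p = aorta_curve.values
    p_norm = p / p.max()

    pel_semi = _semi_axes(spec.pelvis_volume_ml)
    density = np.zeros((schedule.n_frames, nx, nz))
    masks_bool: dict[str, np.ndarray] = {}
    peak_density = 0.0
    kidney_total_peak = 0.0
    for side, sign, vol in (("left", +1.0, spec.volume_left),
                            ("right", -1.0, spec.volume_right)):
        semi = _semi_axes(vol)
        center = (sign * _KIDNEY_OFFSET_X, 0.0)
        if abs(center[0]) + semi[0] > nx * dx / 2.0 or semi[2] > nz * dz / 2.0:
            raise ConfigurationError(
                f"{side} kidney of {vol} mL does not fit in the field of view")
        q, zc = _renal_components(spec, side, aorta_curve, schedule)
        chord = _ellipse_chord(xg, zg, center, (semi[0], semi[2]), semi[1])
        pel_center = (sign * (_KIDNEY_OFFSET_X - semi[0] - pel_semi[0]), 0.0)
        pel_chord = _ellipse_chord(xg, zg, pel_center,
                                   (pel_semi[0], pel_semi[2]), pel_semi[1])
        v_par_mm3 = vol * 1000.0
        v_pel_mm3 = spec.pelvis_volume_ml * 1000.0
        # activity densities per mm^3 (a.u./mL -> /1000 per mm^3)
        density += (q[:, None, None] / 1000.0) * chord[None] \
            + ((zc * v_par_mm3 / v_pel_mm3)[:, None, None] / 1000.0) * pel_chord[None]
        masks_bool[f"{side}_kidney"] = chord > 0
        masks_bool[f"{side}_whole"] = (chord > 0) | (pel_chord > 0)
        masks_bool[f"{side}_background"] = _c_shaped_background(
            xg, zg, center, (semi[0], semi[2]), sign)
        peak_density = max(peak_density, float(q.max()) / 1000.0)
        kidney_total_peak = max(kidney_total_peak,
                                float((vol * (q + zc)).max()))

    heart_center, heart_radius, heart_chord = (0.0, 120.0), 25.0, 60.0
    heart = ((xg - heart_center[0]) ** 2 + (zg - heart_center[1]) ** 2
             ) <= heart_radius ** 2
    density += (0.5 * peak_density * p_norm)[:, None, None] \
        * np.where(heart, heart_chord, 0.0)[None]
    masks_bool["heart"] = heart

    body = ((xg / 90.0) ** 2 + (zg / 185.0) ** 2) <= 1.0
    body_thickness = 150.0
    density += (spec.background_level * peak_density * p_norm)[:, None, None] \
        * np.where(body, body_thickness, 0.0)[None]

    scale = spec.drs_count_scale / kidney_total_peak  # counts per (mL * a.u.)
    lam = density * pixel_area * scale
    truth = PhantomTruth.from_spec(spec)
    rng = np.random.default_rng([spec.seed, 1])
    frames = rng.poisson(lam).astype(np.int32)

    masks = {label: RegionMask(label, m, pixel_area)
             for label, m in masks_bool.items()}
    return DRSStudy(frames=frames, schedule=schedule, pixel_size=pixel_size,
                    masks=masks, truth=truth, spec=spec)


def simulate_study(spec: PhantomSpec, modality: str = "mru", **kwargs):
    """Simulate one study; returns ``(study, truth)``."""
    if modality == "mru":
        study = simulate_mru(spec, **kwargs)
    elif modality == "drs":
        study = simulate_drs(spec, **kwargs)
    else:
        raise InputError("modality must be 'mru' or 'drs'")
    return study, study.truth
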