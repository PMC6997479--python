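"""Split renal function (SRF) estimation.

Three estimators are provided, mirroring routine renography practice:

* **AUC method** — ratio of trapezoid-integrated, background-corrected
  uptake-phase curves of the two kidneys.
* **Rutland-Patlak method** — ordinary least squares on the linearized
  irreversible-uptake model ``Q(t)/P(t) = K·(∫₀ᵗP dτ)/P(t) + V₀``; the
  slope ``K`` is the filtration/uptake constant and SRF is the slope
  ratio.
* **Volumetric SRF** — per-unit-volume uptake constants weighted by each
  kidney's segmented parenchymal volume,
  ``vSRF_L = 100·V_L·k_L/(V_L·k_L + V_R·k_R)``.

All left/right SRF pairs are normalized to sum to exactly 100. Fit and
integration windows default to the early uptake phase (from 20 s to 120 s
after the aortic peak) so that neither method is contaminated by
collecting-system outflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import label as cc_label

from .curves import TimeActivityCurve
from .exceptions import FitError, InputError, ParameterError, UndefinedSRFError

__all__ = [
    "PatlakFit",
    "SRFResult",
    "SegmentedVolumes",
    "auc_srf",
    "patlak_fit",
    "patlak_srf",
    "segment_volume",
    "volumetric_srf",
    "default_uptake_window",
]


@dataclass(frozen=True)
class PatlakFit:
    """Rutland-Patlak regression result for one kidney.

    ``slope_K`` is the uptake constant in s⁻¹ (ratio of renal to aortic
    signal per unit of normalized integrated input), ``intercept_V0`` the
    apparent vascular volume fraction.
    """

    slope_K: float
    intercept_V0: float
    r_squared: float
    window: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ParameterError("fit window must have t_start < t_end")
        if self.n_points < 3:
            raise FitError("Patlak fit requires at least 3 points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise FitError("r_squared outside [0, 1]")


@dataclass
class SRFResult:
    """Split renal function by every available method, percent per side."""

    auc_srf_left: float | None = None
    auc_srf_right: float | None = None
    patlak_srf_left: float | None = None
    patlak_srf_right: float | None = None
    volumetric_srf_left: float | None = None
    volumetric_srf_right: float | None = None
    volume_left: float | None = None
    volume_right: float | None = None
    method_windows: dict | None = None

    def __post_init__(self) -> None:
        for a, b in (("auc_srf_left", "auc_srf_right"),
                     ("patlak_srf_left", "patlak_srf_right"),
                     ("volumetric_srf_left", "volumetric_srf_right")):
            va, vb = getattr(self, a), getattr(self, b)
            if (va is None) != (vb is None):
                raise InputError(f"{a}/{b} must be set together")
            if va is not None:
                if not (0 <= va <= 100 and 0 <= vb <= 100):
                    raise InputError("SRF values must lie in [0, 100]")
                if abs(va + vb - 100.0) > 1e-6:
                    raise InputError("SRF pair must sum to 100")


class SegmentedVolumes(NamedTuple):
    """Kidney volumes (mL) from threshold segmentation; missing side None."""

    volume_left: float | None
    volume_right: float | None
    n_components: int


def _normalized_pair(left: float, right: float) -> tuple[float, float]:
    total = left + right
    if total <= 0:
        raise UndefinedSRFError(
            "combined functional signal of the two kidneys is non-positive")
    s = 100.0 * left / total
    return s, 100.0 - s


def default_uptake_window(aorta_peak_time: float) -> tuple[float, float]:
    """Default uptake-phase window: [peak + 20 s, peak + 120 s]."""
    return (aorta_peak_time + 20.0, aorta_peak_time + 120.0)


def auc_srf(left: TimeActivityCurve, right: TimeActivityCurve,
            window: tuple[float, float]) -> tuple[float, float]:
    """SRF by the area-under-the-curve method.

    Both curves must be background-corrected and share a schedule; the
    trapezoid integrals over ``window`` are ratioed into a percent pair.
    """
    if not left.same_schedule(right):
        raise InputError("left and right curves are on different schedules")
    a_l = left.integral(window)
    a_r = right.integral(window)
    if a_l < 0 or a_r < 0:
        warnings.warn("negative uptake-phase integral floored at 0",
                      stacklevel=2)
        a_l, a_r = max(a_l, 0.0), max(a_r, 0.0)
    return _normalized_pair(a_l, a_r)


def patlak_fit(renal: TimeActivityCurve, aorta: TimeActivityCurve,
               window: tuple[float, float]) -> PatlakFit:
    """Fit the Rutland-Patlak plot over the given uptake window.

    The normalized integrated input ``x = (∫₀ᵗP dτ)/P(t)`` (trapezoid
    cumulative integral from the start of the acquisition) is regressed
    against ``y = Q(t)/P(t)`` by ordinary least squares over the frames in
    ``window``. Frames with non-positive aortic values are dropped with a
    warning; fewer than 3 usable frames is a fit error.
    """
    if not renal.same_schedule(aorta):
        raise InputError("renal and aortic curves are on different schedules")
    t = renal.times
    cum = cumulative_trapezoid(aorta.values, t, initial=0.0)
    sel = (t >= window[0]) & (t <= window[1])
    usable = sel & (aorta.values > 0)
    n_dropped = int(sel.sum() - usable.sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} frames with non-positive aortic "
                      "signal from the Patlak window", stacklevel=2)
    if usable.sum() < 3:
        raise FitError("fewer than 3 usable frames in the Patlak window")
    x = cum[usable] / aorta.values[usable]
    y = renal.values[usable] / aorta.values[usable]
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return PatlakFit(slope_K=float(slope), intercept_V0=float(intercept),
                     r_squared=float(np.clip(r2, 0.0, 1.0)),
                     window=(float(window[0]), float(window[1])),
                     n_points=int(usable.sum()))


def patlak_srf(fit_left: PatlakFit, fit_right: PatlakFit) -> tuple[float, float]:
    """SRF as the ratio of Rutland-Patlak slopes, percent per side.

    Negative slopes are non-physical and floored at zero with a warning.
    """
    k_l, k_r = fit_left.slope_K, fit_right.slope_K
    if not (np.isfinite(k_l) and np.isfinite(k_r)):
        raise FitError("Patlak slopes must be finite")
    if k_l < 0 or k_r < 0:
        warnings.warn("negative Patlak slope floored at 0", stacklevel=2)
        k_l, k_r = max(k_l, 0.0), max(k_r, 0.0)
    return _normalized_pair(k_l, k_r)


def segment_volume(volume_frame: np.ndarray, threshold_fraction: float = 0.5,
                   voxel_volume: float = 1.0) -> SegmentedVolumes:
    """Threshold + connected-component segmentation of a volumetric frame.

    The frame is binarized at ``threshold_fraction`` of its maximum, the
    two largest 26-connected components are kept, and sides are assigned
    by centroid along the first (left-right) axis: larger index = patient
    left. Volumes are voxel count × ``voxel_volume`` (mm³) / 1000, in mL.
    If only one component exists, the other side is reported as None.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ParameterError("threshold_fraction must be in (0, 1)")
    frame = np.asarray(volume_frame, dtype=float)
    if frame.ndim != 3:
        raise InputError("volume frame must be 3-D")
    if not np.any(frame > 0):
        raise InputError("volume frame is empty")
    binary = frame >= threshold_fraction * frame.max()
    labels, n = cc_label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        raise InputError("no components above threshold")
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1][:2] + 1
    comps = [(labels == lab) for lab in order]
    if len(comps) == 1:
        vol = comps[0].sum() * voxel_volume / 1000.0
        centroid_x = np.nonzero(comps[0])[0].mean()
        mid = frame.shape[0] / 2.0
        if centroid_x >= mid:
            return SegmentedVolumes(float(vol), None, int(n))
        return SegmentedVolumes(None, float(vol), int(n))
    cx = [np.nonzero(c)[0].mean() for c in comps]
    left_idx = int(np.argmax(cx))
    vols = [c.sum() * voxel_volume / 1000.0 for c in comps]
    return SegmentedVolumes(float(vols[left_idx]),
                            float(vols[1 - left_idx]), int(n))


def volumetric_srf(k_left_per_volume: float, k_right_per_volume: float,
                   volume_left: float, volume_right: float) -> tuple[float, float]:
    """Volume-weighted SRF from per-unit-volume uptake indices.

    ``vSRF_L = 100·V_L·k_L/(V_L·k_L + V_R·k_R)``. The per-unit-volume
    index is typically the ROI Patlak slope (an AUC-based index can be
    substituted identically). Negative indices are floored at zero.
    """
    if volume_left <= 0 or volume_right <= 0:
        raise ParameterError("volumes must be positive")
    k_l, k_r = k_left_per_volume, k_right_per_volume
    if k_l < 0 or k_r < 0:
        warnings.warn("negative functional index floored at 0", stacklevel=2)
        k_l, k_r = max(k_l, 0.0), max(k_r, 0.0)
    return _normalized_pair(volume_left * k_l, volume_right * k_r)
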