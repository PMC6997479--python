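"""Time–activity curve container and curve-level operations.

The central object is :class:`TimeActivityCurve`: one region's signal
(dynamic MR urography, arbitrary units) or count (scintigraphy, counts per
frame) trace over the acquisition, carrying frame midpoint times and frame
durations. Curves are extracted from dynamic series with region masks,
background-corrected, resampled to uniform time grids and searched for
their filtration peak.

Conventions
-----------
* Scintigraphy (``drs``) ROI curves are **sums** over mask elements: counts
  are extensive.
* MR urography (``mru``) ROI curves are **means**: signal intensity is
  intensive. All downstream split-function quantities are ratios, so the
  normalization cancels.
* Background correction subtracts ``size_ratio × background``; for count
  curves ``size_ratio`` is the ROI-size ratio, for signal curves it is 1.
  Negative corrected values are clipped to zero and the number of clipped
  frames recorded in ``flags["clipped_frames"]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.ndimage import uniform_filter1d

from .exceptions import InputError, ParameterError

__all__ = [
    "TimeActivityCurve",
    "RegionMask",
    "PeakResult",
    "extract_curve",
    "background_subtract",
    "resample_uniform",
    "find_peak",
]


@dataclass
class TimeActivityCurve:
    """One region's trace over a dynamic acquisition.

    Parameters
    ----------
    times
        Frame midpoint times in seconds, strictly increasing.
    durations
        Frame durations in seconds, positive.
    values
        Signal (a.u.) or counts per frame; finite.
    region_label
        Anatomic label of the source region (e.g. ``"left_kidney"``).
    modality
        ``"mru"`` or ``"drs"`` where known.
    flags
        Free-form QC annotations accumulated by curve operations.
    """

    times: np.ndarray
    durations: np.ndarray
    values: np.ndarray
    region_label: str | None = None
    modality: str | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.durations = np.asarray(self.durations, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.times.ndim == self.durations.ndim == self.values.ndim == 1):
            raise InputError("times, durations and values must be 1-D")
        if not (len(self.times) == len(self.durations) == len(self.values)):
            raise InputError("times, durations and values must have equal length")
        if len(self.times) == 0:
            raise InputError("curve must contain at least one frame")
        if np.any(np.diff(self.times) <= 0):
            raise InputError("frame times must be strictly increasing")
        if np.any(self.durations <= 0):
            raise InputError("frame durations must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InputError("curve values must be finite")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def start(self) -> float:
        """Time of the first frame midpoint (s)."""
        return float(self.times[0])

    @property
    def end(self) -> float:
        """Time of the last frame midpoint (s)."""
        return float(self.times[-1])

    @property
    def span(self) -> float:
        """Elapsed time between first and last midpoint (s)."""
        return self.end - self.start

    def value_at(self, t: float) -> float:
        """Linearly interpolated value at time ``t`` (clamped to the span)."""
        return float(np.interp(t, self.times, self.values))

    def integral(self, window: tuple[float, float] | None = None) -> float:
        """Trapezoid integral of the curve over ``window`` (default: full span)."""
        if window is None:
            return float(np.trapezoid(self.values, self.times))
        t0, t1 = window
        if t1 <= t0:
            raise ParameterError("integration window must have t_start < t_end")
        sel = (self.times >= t0) & (self.times <= t1)
        if sel.sum() < 2:
            raise InputError("integration window contains fewer than 2 frames")
        return float(np.trapezoid(self.values[sel], self.times[sel]))

    def same_schedule(self, other: "TimeActivityCurve", atol: float = 1e-6) -> bool:
        return self.n_frames == other.n_frames and bool(
            np.allclose(self.times, other.times, atol=atol)
        )

    def with_values(self, values: np.ndarray, **updates) -> "TimeActivityCurve":
        """Copy of this curve with new values (and optional field updates)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       flags=dict(self.flags), **updates)


@dataclass
class RegionMask:
    """Region of interest on a dynamic series' spatial grid.

    ``mask`` is a boolean array over the spatial dimensions of the series
    (2-D for planar scintigraphy, 3-D for MR volumes); ``element_size`` is
    the pixel area (mm²) or voxel volume (mm³).
    """

    label: str
    mask: np.ndarray
    element_size: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim not in (2, 3):
            raise InputError("mask must be 2-D (planar) or 3-D (volumetric)")
        if not self.mask.any():
            raise InputError(f"mask '{self.label}' is empty")
        if self.element_size <= 0:
            raise ParameterError("element_size must be positive")

    @property
    def n_elements(self) -> int:
        return int(self.mask.sum())

    @property
    def indices(self) -> tuple[np.ndarray, ...]:
        """Member indices on the series grid (``np.nonzero`` layout)."""
        return np.nonzero(self.mask)


class PeakResult(NamedTuple):
    """Location of the (smoothed) global curve maximum."""

    t_peak: float
    value: float
    flat: bool = False


def extract_curve(series, mask: RegionMask, schedule=None,
                  modality: str | None = None) -> TimeActivityCurve:
    """Extract a region's time–activity curve from a dynamic series.

    ``series`` may be a study object exposing ``frames``, ``schedule`` and
    ``modality`` (as produced by :mod:`renoquant.phantom`) or a raw array of
    shape ``(n_frames, *spatial)`` together with an explicit ``schedule``.

    The per-frame statistic is the ROI **mean** for MR (intensive signal)
    and the ROI **sum** for scintigraphy (extensive counts).
    """
    if hasattr(series, "frames"):
        frames = series.frames
        schedule = schedule if schedule is not None else series.schedule
        modality = modality if modality is not None else series.modality
    else:
        frames = np.asarray(series)
        if schedule is None:
            raise InputError("schedule required when series is a raw array")
    if modality not in ("mru", "drs"):
        raise InputError(f"modality must be 'mru' or 'drs', got {modality!r}")
    if frames.shape[1:] != mask.mask.shape:
        raise InputError(
            f"mask shape {mask.mask.shape} does not match series spatial shape "
            f"{frames.shape[1:]}")
    roi = frames[:, mask.mask]
    values = roi.mean(axis=1) if modality == "mru" else roi.sum(axis=1)
    return TimeActivityCurve(
        times=schedule.midpoints,
        durations=schedule.frame_durations,
        values=values,
        region_label=mask.label,
        modality=modality,
    )


def background_subtract(kidney: TimeActivityCurve,
                        background: TimeActivityCurve,
                        size_ratio: float | None = None) -> TimeActivityCurve:
    """Background-correct a kidney curve.

    ``corrected(t) = kidney(t) − size_ratio · background(t)``.

    When ``size_ratio`` is None it defaults to 1 for MR signal curves; for
    count curves it must be supplied as kidney-ROI size / background-ROI
    size (counts scale with ROI area). Negative corrected values are
    clipped to 0; the number of clipped frames is recorded in
    ``flags["clipped_frames"]``.
    """
    if not kidney.same_schedule(background):
        raise InputError("kidney and background curves are on different schedules")
    if size_ratio is None:
        if kidney.modality == "drs":
            raise InputError(
                "size_ratio is required for count (drs) curves: pass kidney "
                "ROI size divided by background ROI size")
        size_ratio = 1.0
    if size_ratio < 0:
        raise ParameterError("size_ratio must be non-negative")
    corrected = kidney.values - size_ratio * background.values
    n_clipped = int((corrected < 0).sum())
    out = kidney.with_values(np.clip(corrected, 0.0, None))
    out.flags["background_corrected"] = True
    out.flags["clipped_frames"] = n_clipped
    return out


def roi_size_ratio(kidney: RegionMask, background: RegionMask) -> float:
    """Kidney-to-background ROI size ratio for count-curve correction."""
    return kidney.n_elements / background.n_elements


def resample_uniform(curve: TimeActivityCurve, dt: float) -> TimeActivityCurve:
    """Resample a curve onto a uniform grid by linear interpolation.

    The grid covers the original midpoint span; both endpoints are kept
    exactly (when the span is not an integer multiple of ``dt`` the final
    point is appended at the original end time). Needed because the MR
    urography protocol switches frame rate mid-acquisition.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    if curve.n_frames < 2:
        raise InputError("resampling requires at least 2 frames")
    t0, t1 = curve.start, curve.end
    n = int(np.floor((t1 - t0) / dt + 1e-9))
    grid = t0 + dt * np.arange(n + 1)
    if grid[-1] < t1 - 1e-9 * max(1.0, abs(t1)):
        grid = np.append(grid, t1)
    else:
        grid[-1] = t1
    values = np.interp(grid, curve.times, curve.values)
    durations = np.full(grid.shape, dt)
    if len(grid) > 1:
        durations[-1] = max(grid[-1] - grid[-2], 1e-12)
    return TimeActivityCurve(
        times=grid, durations=durations, values=values,
        region_label=curve.region_label, modality=curve.modality,
        flags=dict(curve.flags))


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Moving average with nearest-edge padding (odd ``window``)."""
    if window < 1 or window % 2 == 0:
        raise ParameterError("smooth window must be odd and >= 1")
    if window == 1:
        return np.asarray(values, dtype=float)
    return uniform_filter1d(np.asarray(values, dtype=float), size=window,
                            mode="nearest")


def find_peak(curve: TimeActivityCurve, smooth_window: int = 5) -> PeakResult:
    """Locate the global maximum of the moving-average-smoothed curve.

    Ties break toward the earliest time. A flat curve returns the first
    frame with ``flat=True``.
    """
    sm = smooth(curve.values, smooth_window)
    if np.ptp(sm) == 0:
        return PeakResult(t_peak=curve.start, value=float(sm[0]), flat=True)
    i = int(np.argmax(sm))
    return PeakResult(t_peak=float(curve.times[i]), value=float(sm[i]))
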