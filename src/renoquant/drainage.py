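"""Drainage-curve classification and quantitative drainage metrics.

A whole-kidney (parenchyma plus collecting system) time–activity curve is
classified into one of three patterns, after O'Reilly's diuretic-renogram
scheme:

* **normal** — the signal declines after the filtration peak;
* **borderline** — the signal plateaus after the peak;
* **accumulation** — the signal keeps rising to the end of the study.

The decision rule is an explicit operationalization of the visual
definitions: let ``t_peak`` be the smoothed global maximum and
``r = mean(last end_window)/peak``; the curve is *accumulation* when the
peak falls inside the final ``end_window`` (still rising at study end),
otherwise *normal* when ``r ≤ 1 − decline_threshold``, otherwise
*borderline*. The defaults (decline_threshold 0.10, end_window 60 s) are
configurable — pattern boundaries are genuinely ambiguous in clinical
reading.

Quantitative metrics follow nuclear-medicine convention:

* **NORA** (normalized residual activity): late activity divided by the
  mean 1–2 min activity; values above 1 indicate retention.
* **ROE** (renal output efficiency): ``100·(1 − R(t)/U(t))`` where
  ``U(t) = K·∫₀ᵗP dτ`` is the Patlak-modelled cumulative tracer input to
  the kidney and ``R(t)`` the residual whole-kidney activity.
* **Tmax**: time of the renogram maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .curves import TimeActivityCurve, find_peak
from .exceptions import EvaluationError, ParameterError
from .srf import PatlakFit

__all__ = [
    "DrainageResult",
    "classify_drainage",
    "nora",
    "output_efficiency",
    "tmax",
    "assess_drainage",
    "DRS_READING_LABELS",
]

#: mapping of traditional scintigraphic reading labels onto the common
#: three-pattern vocabulary used by both modalities
DRS_READING_LABELS = {"normal": "normal", "borderline": "borderline",
                      "poor": "accumulation"}


@dataclass
class DrainageResult:
    """Pattern and metrics for one kidney's drainage curve."""

    pattern: str
    t_max: float
    nora: float | None = None
    roe: float | None = None
    end_to_peak_ratio: float | None = None
    flags: list[str] = field(default_factory=list)


def classify_drainage(curve: TimeActivityCurve,
                      decline_threshold: float = 0.10,
                      end_window: float = 60.0,
                      smooth_window: int = 5) -> str:
    """Classify a drainage curve as normal, borderline or accumulation."""
    pattern, _ = _classify(curve, decline_threshold, end_window, smooth_window)
    return pattern


def _classify(curve, decline_threshold, end_window, smooth_window):
    if not 0.0 < decline_threshold < 1.0:
        raise ParameterError("decline_threshold must be in (0, 1)")
    if curve.span < 2 * end_window:
        raise ParameterError("curve must span at least twice the end window")
    if np.all(curve.values == 0):
        raise EvaluationError("all-zero curve cannot be classified")
    flags: list[str] = []
    peak = find_peak(curve, smooth_window)
    if peak.flat:
        flags.append("flat_curve")
        return "borderline", flags
    end_mask = curve.times >= curve.end - end_window
    r = float(curve.values[end_mask].mean()) / peak.value
    flags.append(f"end_to_peak_ratio={r:.4f}")
    if peak.t_peak >= curve.end - end_window:
        return "accumulation", flags
    if r <= 1.0 - decline_threshold:
        return "normal", flags
    return "borderline", flags


def nora(curve: TimeActivityCurve, t_eval: float | None = None,
         ref_window: tuple[float, float] = (60.0, 120.0)) -> float:
    """Normalized residual activity.

    ``NORA = curve(t_eval) / mean(curve over ref_window)``; ``t_eval``
    defaults to 20 min or the end of the study if shorter, the reference
    window to 1–2 min after injection.
    """
    if t_eval is None:
        t_eval = min(1200.0, curve.end)
    if not curve.start <= t_eval <= curve.end:
        raise ParameterError("t_eval outside the curve span")
    sel = (curve.times >= ref_window[0]) & (curve.times <= ref_window[1])
    if not sel.any():
        raise ParameterError("reference window contains no frames")
    ref = float(curve.values[sel].mean())
    if ref <= 0:
        raise EvaluationError("non-positive reference activity")
    return curve.value_at(t_eval) / ref


def output_efficiency(curve: TimeActivityCurve, fit: PatlakFit,
                      aorta: TimeActivityCurve,
                      t_eval: float | None = None) -> float:
    """Renal output efficiency at ``t_eval`` (default: end of study), percent.

    The Patlak-modelled cumulative input ``U(t) = K·∫₀ᵗ P dτ`` is compared
    with the residual whole-kidney activity ``R(t)``:
    ``ROE = 100·(1 − R/U)``. The result is at most 100 (complete
    drainage); it can be negative when the residual exceeds the modelled
    input (callers should flag this).
    """
    if t_eval is None:
        t_eval = curve.end
    if not curve.start <= t_eval <= curve.end:
        raise ParameterError("t_eval outside the curve span")
    if fit.slope_K <= 0:
        raise EvaluationError("output efficiency requires a positive uptake slope")
    cum = cumulative_trapezoid(aorta.values, aorta.times, initial=0.0)
    u = fit.slope_K * float(np.interp(t_eval, aorta.times, cum))
    if u <= 0:
        raise EvaluationError("modelled cumulative input is non-positive")
    roe = 100.0 * (1.0 - curve.value_at(t_eval) / u)
    return min(roe, 100.0)


def tmax(curve: TimeActivityCurve, smooth_window: int = 5) -> float:
    """Time of the renogram maximum (s); delegates to the peak finder."""
    return find_peak(curve, smooth_window).t_peak


def assess_drainage(curve: TimeActivityCurve,
                    fit: PatlakFit | None = None,
                    aorta: TimeActivityCurve | None = None,
                    decline_threshold: float = 0.10,
                    end_window: float = 60.0,
                    smooth_window: int = 5,
                    t_eval: float | None = None) -> DrainageResult:
    """Full drainage report: pattern, Tmax, NORA and (if a Patlak fit and
    aortic curve are supplied) output efficiency."""
    pattern, flags = _classify(curve, decline_threshold, end_window,
                               smooth_window)
    peak = find_peak(curve, smooth_window)
    if peak.t_peak >= curve.times[-1]:
        flags.append("no_peak")
    result = DrainageResult(pattern=pattern, t_max=peak.t_peak, flags=flags)
    end_mask = curve.times >= curve.end - end_window
    if peak.value > 0:
        result.end_to_peak_ratio = float(curve.values[end_mask].mean()) / peak.value
    try:
        result.nora = nora(curve, t_eval=t_eval)
    except (EvaluationError, ParameterError) as exc:
        flags.append(f"nora_unavailable: {exc}")
    if fit is not None and aorta is not None:
        try:
            result.roe = output_efficiency(curve, fit, aorta, t_eval=t_eval)
            if result.roe < 0:
                flags.append("negative_roe")
        except EvaluationError as exc:
            flags.append(f"roe_unavailable: {exc}")
    return result
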