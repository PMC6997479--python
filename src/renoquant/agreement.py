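"""Method-agreement statistics for paired renography measurements.

Implements the comparison layer used to judge whether two renography
techniques (or two readers) agree:

* **Bland-Altman limits of agreement** for paired continuous
  measurements (split renal function percentages): mean difference ±
  1.96 sample standard deviations, with confidence intervals for the
  mean and for each limit.
* **Cohen's kappa** (unweighted by default, optional linear/quadratic
  weights) on a 3×3 drainage-pattern contingency table, with a
  large-sample confidence interval and the conventional interpretation
  bands (null / slight / fair / moderate / substantial / almost perfect).
* **Diagnostic effectiveness** (proportion correctly categorized = the
  table trace over its total) and misclassification rate (its
  complement).
* **Spearman rank correlation** with ``r² = ρ²``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EvaluationError, InputError

__all__ = [
    "PairedMeasurements",
    "BlandAltmanResult",
    "ContingencyTable3x3",
    "KappaResult",
    "bland_altman",
    "bland_altman_from_stats",
    "bland_altman_plot",
    "cohens_kappa",
    "diagnostic_effectiveness",
    "spearman_r2",
]

DEFAULT_CATEGORIES = ("normal", "borderline", "accumulation")

#: interpretation bands for kappa
_KAPPA_BANDS = ((0.01, "null"), (0.20, "slight"), (0.40, "fair"),
                (0.60, "moderate"), (0.80, "substantial"),
                (np.inf, "almost perfect"))


@dataclass
class PairedMeasurements:
    """Paired measurements of the same quantity by two methods."""

    method_a: np.ndarray
    method_b: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=float)
        self.method_b = np.asarray(self.method_b, dtype=float)
        if self.method_a.shape != self.method_b.shape or self.method_a.ndim != 1:
            raise InputError("paired measurements must be equal-length 1-D")
        if len(self.method_a) < 2:
            raise InputError("at least 2 pairs are required")
        if not (np.all(np.isfinite(self.method_a))
                and np.all(np.isfinite(self.method_b))):
            raise InputError("measurements must be finite")
        if self.ids is None:
            self.ids = np.arange(len(self.method_a))

    @property
    def differences(self) -> np.ndarray:
        return self.method_a - self.method_b

    @property
    def means(self) -> np.ndarray:
        return (self.method_a + self.method_b) / 2.0


@dataclass(frozen=True)
class BlandAltmanResult:
    """Limits of agreement mean_diff ± 1.96·sd_diff with their CIs."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int | None = None
    ci_mean: tuple[float, float] | None = None
    ci_lower_limit: tuple[float, float] | None = None
    ci_upper_limit: tuple[float, float] | None = None


def _ba_from_moments(mean: float, sd: float, n: int | None) -> BlandAltmanResult:
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    ci_mean = ci_lo = ci_hi = None
    if n is not None and n >= 2:
        half_mean = 1.96 * sd / np.sqrt(n)
        half_limit = 1.96 * sd * np.sqrt(3.0 / n)
        ci_mean = (mean - half_mean, mean + half_mean)
        ci_lo = (lo - half_limit, lo + half_limit)
        ci_hi = (hi - half_limit, hi + half_limit)
    return BlandAltmanResult(mean_diff=mean, sd_diff=sd, loa_lower=lo,
                             loa_upper=hi, n=n, ci_mean=ci_mean,
                             ci_lower_limit=ci_lo, ci_upper_limit=ci_hi)


def bland_altman(pairs: PairedMeasurements) -> BlandAltmanResult:
    """Bland-Altman analysis of paired method differences ``a − b``.

    The sample standard deviation uses the n−1 denominator; limits are
    mean ± 1.96·SD, the CI of the mean is ± 1.96·SD/√n, and the CI of
    each limit ± 1.96·SD·√(3/n).
    """
    d = pairs.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return _ba_from_moments(mean, sd, len(d))


def bland_altman_from_stats(mean_diff: float, sd_diff: float,
                            n: int | None = None) -> BlandAltmanResult:
    """Limits of agreement recomputed from a reported mean/SD pair."""
    if sd_diff < 0:
        raise InputError("sd_diff must be non-negative")
    return _ba_from_moments(float(mean_diff), float(sd_diff), n)


def bland_altman_plot(pairs: PairedMeasurements, ax=None, **scatter_kw):
    """Scatter of differences against pair means with the agreement limits."""
    import matplotlib.pyplot as plt

    res = bland_altman(pairs)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pairs.means, pairs.differences, **scatter_kw)
    for y, style in ((res.mean_diff, "-"), (res.loa_lower, "--"),
                     (res.loa_upper, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (a − b)")
    return ax


@dataclass
class ContingencyTable3x3:
    """3×3 cross-classification of drainage patterns.

    Rows index the reference method's category, columns the test
    method's; default labels are the three drainage patterns.
    """

    counts: np.ndarray
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (3, 3):
            raise InputError("contingency table must be 3x3")
        if np.any(self.counts < 0) or not np.issubdtype(
                self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)) or np.any(
                    self.counts < 0):
                raise InputError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)
        if self.counts.sum() == 0:
            raise InputError("contingency table is empty")
        if len(self.categories) != 3:
            raise InputError("three category labels required")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, reference, test,
                    categories: tuple[str, ...] = DEFAULT_CATEGORIES
                    ) -> "ContingencyTable3x3":
        idx = {c: i for i, c in enumerate(categories)}
        counts = np.zeros((3, 3), dtype=int)
        for r, t in zip(reference, test, strict=True):
            counts[idx[r], idx[t]] += 1
        return cls(counts, categories)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.categories),
                            columns=list(self.categories))


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with agreement proportions and interpretation."""

    observed_agreement: float
    expected_agreement: float
    kappa: float
    ci95: tuple[float, float]
    interpretation: str


def interpret_kappa(kappa: float) -> str:
    for upper, label in _KAPPA_BANDS:
        if kappa < upper or upper is np.inf:
            return label
    return "almost perfect"


def cohens_kappa(table: ContingencyTable3x3,
                 weights: str | None = None) -> KappaResult:
    """Cohen's kappa for a 3×3 table.

    ``Po = trace/N``, ``Pe = Σ row_i·col_i / N²``,
    ``kappa = (Po − Pe)/(1 − Pe)``; the 95% CI uses the simple
    large-sample standard error ``√(Po(1−Po)/(N(1−Pe)²))``. Optional
    ``weights`` ("linear" or "quadratic") give weighted kappa for ordered
    categories; the unweighted statistic is the default for the three
    nominal drainage patterns.
    """
    counts = table.counts.astype(float)
    n = counts.sum()
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row > 0).sum() < 2 and (col > 0).sum() < 2:
        raise EvaluationError("kappa requires at least two used categories")
    if weights is None:
        w = np.eye(3)
    elif weights in ("linear", "quadratic"):
        i, j = np.indices((3, 3))
        d = np.abs(i - j) / 2.0
        w = 1.0 - (d if weights == "linear" else d ** 2)
    else:
        raise InputError("weights must be None, 'linear' or 'quadratic'")
    po = float((w * counts).sum() / n)
    pe = float((w * np.outer(row, col)).sum() / n ** 2)
    if pe >= 1.0:
        raise EvaluationError(
            "expected agreement is 1 (single-category table): kappa undefined")
    kappa = (po - pe) / (1.0 - pe)
    se = np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    return KappaResult(observed_agreement=po, expected_agreement=pe,
                       kappa=float(kappa),
                       ci95=(float(kappa - 1.96 * se), float(kappa + 1.96 * se)),
                       interpretation=interpret_kappa(float(kappa)))


def diagnostic_effectiveness(table: ContingencyTable3x3
                             ) -> tuple[float, float]:
    """(effectiveness, misclassification): trace/N and its complement."""
    eff = float(np.trace(table.counts)) / table.n
    return eff, 1.0 - eff


def spearman_r2(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) and its square."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise InputError("spearman_r2 requires equal-length 1-D data, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise EvaluationError("correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    return rho, rho ** 2
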