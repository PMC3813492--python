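"""Population-splitting (PS) methods for bimodal fluorescence distributions.

A PS method places a cutoff in value space and reports every cell strictly
above it as the small ("ON") subpopulation, expressed as a percentage of the
total population.  Four methods are provided:

``default``
    Normal Q-Q plot regression.  The bulk ("OFF") subpopulation traces a
    straight line in a normal Q-Q plot whose slope equals its standard
    deviation.  An ordinary least-squares fit restricted to the central
    region of the data estimates that slope, and the cutoff is placed at
    ``median + z(p_conf) * slope`` — by default the one-sided 99.5% point,
    ``median + 2.576 * SD``.
``manual``
    A user-supplied cutoff (replaces interactive cursor placement).
``boxplot1.5`` / ``boxplot3``
    Tukey boxplot outlier fences: ``cutoff = Q3 + k * IQR`` with k = 1.5
    (mild outliers) or k = 3 (extreme outliers), quartiles taken as Tukey
    hinges.

All methods are translation/scale equivariant and assign boundary ties to
the large subpopulation (strict ``>`` above the cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "QQPlot",
    "RegressionRegion",
    "FiveNumberSummary",
    "SplitResult",
    "qq_points",
    "tukey_hinges",
    "split_boxplot",
    "split_manual",
    "split_default",
]

MethodName = Literal["default", "manual", "boxplot1.5", "boxplot3"]


@dataclass(frozen=True)
class QQPlot:
    """Sorted observations paired with theoretical standard-normal quantiles.

    Plotting positions follow the normal-scores convention: rank i (1-based)
    of n maps to ``(i - 0.5)/n`` for n > 10 and ``(i - 3/8)/(n + 1/4)`` for
    n <= 10; the theoretical quantile is the standard-normal inverse CDF of
    that position.
    """

    sorted_values: np.ndarray
    theor_quantiles: np.ndarray

    def __post_init__(self) -> None:
        if len(self.sorted_values) != len(self.theor_quantiles):
            raise ValueError("sorted_values and theor_quantiles must have equal length")


@dataclass(frozen=True)
class RegressionRegion:
    """Value-space bounds delimiting the large subpopulation's approximate IQR."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"regression region requires lo < hi, got ({self.lo}, {self.hi})")


@dataclass(frozen=True)
class FiveNumberSummary:
    min: float
    hinge_lower: float
    median: float
    hinge_upper: float
    max: float

    @property
    def iqr(self) -> float:
        return self.hinge_upper - self.hinge_lower


@dataclass
class SplitResult:
    """Outcome of one population-splitting method.

    ``small_pct`` is the percentage of records strictly above ``cutoff``;
    ``small_mask`` marks those records in input order.  ``slope`` and
    ``median_large`` are populated by the default (Q-Q regression) method,
    ``q1``/``q3``/``iqr`` by the boxplot methods.
    """

    method: str
    cutoff: float
    n_total: int
    n_small: int
    small_pct: float
    small_mask: np.ndarray = field(repr=False)
    slope: Optional[float] = None
    median_large: Optional[float] = None
    q1: Optional[float] = None
    q3: Optional[float] = None
    iqr: Optional[float] = None

    def to_dict(self) -> dict:
        """JSON-serializable summary (mask omitted)."""
        out = {
            "method": self.method,
            "cutoff": float(self.cutoff),
            "n_total": int(self.n_total),
            "n_small": int(self.n_small),
            "small_pct": float(self.small_pct),
        }
        for key in ("slope", "median_large", "q1", "q3", "iqr"):
            val = getattr(self, key)
            if val is not None:
                out[key] = float(val)
        return out


def _as_values(values) -> np.ndarray:
    """Accept a bare sequence or any object exposing ``.agv_values()``."""
    if hasattr(values, "agv_values"):
        values = values.agv_values()
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("values contain non-finite entries")
    return arr


def qq_points(values) -> QQPlot:
    """Build the normal Q-Q plot coordinates for a sample."""
    arr = _as_values(values)
    n = arr.size
    if n < 2:
        raise ValueError("need at least 2 values for a Q-Q plot")
    srt = np.sort(arr)
    i = np.arange(1, n + 1)
    if n > 10:
        pos = (i - 0.5) / n
    else:
        pos = (i - 3.0 / 8.0) / (n + 0.25)
    return QQPlot(sorted_values=srt, theor_quantiles=stats.norm.ppf(pos))


def tukey_hinges(values) -> FiveNumberSummary:
    """Five-number summary with Tukey hinges.

    Hinges are the medians of the lower and upper halves of the sorted data;
    when n is odd each half includes the overall median position.  This is
    the boxplot-statistics rule (``fivenum``-style) rather than an
    interpolated quantile.
    """
    arr = _as_values(values)
    n = arr.size
    if n < 1:
        raise ValueError("need at least 1 value")
    srt = np.sort(arr)
    m = (n + 1) // 2  # lower-half size, includes median position for odd n
    lower = srt[:m]
    upper = srt[n - m:]
    return FiveNumberSummary(
        min=float(srt[0]),
        hinge_lower=float(np.median(lower)),
        median=float(np.median(srt)),
        hinge_upper=float(np.median(upper)),
        max=float(srt[-1]),
    )


def _make_result(method: str, arr: np.ndarray, cutoff: float, **extra) -> SplitResult:
    mask = arr > cutoff
    n_small = int(mask.sum())
    n_total = arr.size
    return SplitResult(
        method=method,
        cutoff=float(cutoff),
        n_total=n_total,
        n_small=n_small,
        small_pct=100.0 * n_small / n_total,
        small_mask=mask,
        **extra,
    )


def split_boxplot(values, k: float = 1.5) -> SplitResult:
    """Split with a Tukey boxplot upper fence: cutoff = Q3 + k * IQR.

    k = 1.5 corresponds to mild-outlier detection (``boxplot1.5``) and
    k = 3 to extreme-outlier detection (``boxplot3``).
    """
    arr = _as_values(values)
    if arr.size < 4:
        raise ValueError("too few cells for quartile estimation (need n >= 4)")
    if k <= 0:
        raise ValueError("fence multiplier k must be positive")
    fns = tukey_hinges(arr)
    cutoff = fns.hinge_upper + k * fns.iqr
    name = f"boxplot{k:g}"
    return _make_result(name, arr, cutoff, q1=fns.hinge_lower, q3=fns.hinge_upper, iqr=fns.iqr)


def split_manual(values, cutoff: float) -> SplitResult:
    """Split at a user-chosen cutoff (strictly-above convention)."""
    arr = _as_values(values)
    if arr.size < 1:
        raise ValueError("empty dataset")
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return _make_result("manual", arr, float(cutoff))


def split_default(
    values,
    region: Union[RegressionRegion, tuple, Literal["auto"]] = "auto",
    p_conf: float = 0.995,
) -> SplitResult:
    """Normal Q-Q regression split.

    The slope of an OLS fit of the sorted values on their theoretical normal
    quantiles, restricted to observations inside ``region``, estimates the
    standard deviation of the large subpopulation.  ``region="auto"``
    resolves to the value bounds at the 25th and 75th percentiles of the
    full data — the large subpopulation's approximate interquartile range
    whenever the small subpopulation is a minority.  The cutoff is
    ``median + z(p_conf) * slope`` (z(0.995) = 2.576), and every value
    strictly above it belongs to the small subpopulation.
    """
    arr = _as_values(values)
    if arr.size < 20:
        raise ValueError("need at least 20 values for the Q-Q regression split")
    if not 0.5 < p_conf < 1.0:
        raise ValueError("p_conf must lie in (0.5, 1)")

    qq = qq_points(arr)
    if region == "auto":
        lo, hi = np.percentile(arr, [25.0, 75.0])
        region = RegressionRegion(float(lo), float(hi))
    elif isinstance(region, tuple):
        region = RegressionRegion(*map(float, region))

    sel = (qq.sorted_values >= region.lo) & (qq.sorted_values <= region.hi)
    if int(sel.sum()) < 10:
        raise ValueError("regression region too small (fewer than 10 points inside)")

    slope, _intercept = np.polyfit(qq.theor_quantiles[sel], qq.sorted_values[sel], 1)
    if slope <= 0:
        raise ValueError("degenerate regression (slope <= 0); region is constant or non-monotone")

    median_large = float(np.median(arr))
    cutoff = median_large + stats.norm.ppf(p_conf) * slope
    return _make_result("default", arr, cutoff, slope=float(slope), median_large=median_large)


_SPLITTERS = {
    "default": split_default,
    "manual": split_manual,
    "boxplot1.5": lambda values, **kw: split_boxplot(values, k=1.5),
    "boxplot3": lambda values, **kw: split_boxplot(values, k=3.0),
}


def split(values, method: MethodName, **params) -> SplitResult:
    """Dispatch to a splitter by name.

    ``manual`` requires ``cutoff=...``; ``default`` accepts ``region`` and
    ``p_conf``.
    """
    try:
        fn = _SPLITTERS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; valid: {sorted(_SPLITTERS)}"
        ) from None
    if method.startswith("boxplot"):
        return fn(values)
    return fn(values, **params)
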