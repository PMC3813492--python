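"""Distribution-independent descriptors used for method comparison.

Unlike the population-splitting methods these summaries do not estimate a
subpopulation size; they characterize the whole distribution and are kept
for side-by-side comparison output:

* ``mean`` — arithmetic mean.
* ``p95`` — 95th percentile, linear interpolation of order statistics
  (h = (n-1)p + 1, the numpy/R type-7 rule).
* ``boosted_mean`` — mean of all values between the 75th and 95th
  percentiles (inclusive bounds).
* ``top5_mean`` — mean of the ceil(0.05 n) largest values.

A percentile-wise treatment/control comparison (P-P percentage difference
profile) is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .splitters import _as_values

__all__ = [
    "DescriptorResult",
    "PercentileDiffProfile",
    "DESCRIPTOR_NAMES",
    "descriptor",
    "pp_percentile_differences",
]

DESCRIPTOR_NAMES = ("mean", "p95", "boosted_mean", "top5_mean")


@dataclass(frozen=True)
class DescriptorResult:
    name: str
    value: float

    def to_dict(self) -> dict:
        return {"name": self.name, "value": float(self.value)}


@dataclass(frozen=True)
class PercentileDiffProfile:
    """Percent difference of treatment vs control quantiles on a probability grid."""

    percentiles: np.ndarray
    diff_pct: np.ndarray


def descriptor(values, name: str) -> DescriptorResult:
    """Compute one named descriptor. See module docstring for definitions."""
    if name not in DESCRIPTOR_NAMES:
        raise ValueError(f"unknown descriptor {name!r}; valid: {list(DESCRIPTOR_NAMES)}")
    arr = _as_values(values)
    n = arr.size
    if name == "mean":
        if n < 1:
            raise ValueError("need at least 1 value for the mean")
        return DescriptorResult("mean", float(np.mean(arr)))
    if n < 20:
        raise ValueError(f"need at least 20 values for {name!r} (percentile-based)")
    if name == "p95":
        return DescriptorResult("p95", float(np.percentile(arr, 95)))
    if name == "boosted_mean":
        lo, hi = np.percentile(arr, [75, 95])
        sel = arr[(arr >= lo) & (arr <= hi)]
        return DescriptorResult("boosted_mean", float(np.mean(sel)))
    # top5_mean
    n_top = int(np.ceil(0.05 * n))
    top = np.sort(arr)[-n_top:]
    return DescriptorResult("top5_mean", float(np.mean(top)))


def pp_percentile_differences(
    treatment, control, grid=None
) -> PercentileDiffProfile:
    """Percentile-wise percent difference between treatment and control.

    ``diff_pct(p) = 100 * (Q_treat(p) - Q_ctrl(p)) / Q_ctrl(p)`` on a grid
    of probabilities (default 0.01 ... 0.99 in steps of 0.01), quantiles by
    linear interpolation.  Raises if any control quantile on the grid is
    zero (percent difference undefined).
    """
    t = _as_values(treatment)
    c = _as_values(control)
    if t.size < 100 or c.size < 100:
        raise ValueError("need at least 100 values in each sample")
    if grid is None:
        grid = np.arange(1, 100) / 100.0
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a 1-D sequence of probabilities")
    if np.any(grid <= 0) or np.any(grid >= 1) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing within (0, 1)")

    q_t = np.percentile(t, 100 * grid)
    q_c = np.percentile(c, 100 * grid)
    zero = q_c == 0
    if np.any(zero):
        p_bad = grid[zero][0]
        raise ValueError(f"control quantile is zero at percentile {100 * p_bad:g}%")
    return PercentileDiffProfile(percentiles=grid, diff_pct=100.0 * (q_t - q_c) / q_c)
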