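"""Bootstrap confidence intervals for splitter and descriptor estimates.

Replicates are drawn by sampling the data with replacement and re-applying
the estimator with its parameters held fixed.  Two interval flavors:

* ``normal`` — mean(replicates) +/- z((1+level)/2) * SD(replicates), the
  normal-approximation interval (z = 1.96 at the 95% level);
* ``percentile`` — empirical (1-level)/2 and (1+level)/2 quantiles of the
  replicates, linear interpolation.

A replicate on which the estimator fails (e.g. a degenerate Q-Q regression
on a resampled dataset) is recorded as missing; more than 20% missing
aborts with an error.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
from scipy import stats

from .splitters import _as_values

__all__ = ["BootstrapCI", "bootstrap_estimates", "ci_normal", "ci_percentile", "bootstrap_ci"]

MAX_MISSING_FRACTION = 0.2


@dataclass
class BootstrapCI:
    estimator_name: str
    point_estimate: float
    replicate_estimates: np.ndarray = field(repr=False)
    n_reps: int
    level: float
    flavor: str
    lower: float
    upper: float

    def to_dict(self) -> dict:
        return {
            "estimator_name": self.estimator_name,
            "point_estimate": float(self.point_estimate),
            "n_reps": int(self.n_reps),
            "level": float(self.level),
            "flavor": self.flavor,
            "lower": float(self.lower),
            "upper": float(self.upper),
            "replicate_estimates": [
                None if math.isnan(v) else float(v) for v in self.replicate_estimates
            ],
        }


def bootstrap_estimates(
    values,
    estimator: Callable[[np.ndarray], float],
    reps: int,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Resample with replacement and re-apply ``estimator`` ``reps`` times.

    ``estimator`` maps a value array to a scalar and must be deterministic
    given its data (manual cutoffs / regression regions are fixed
    parameters, not re-chosen per replicate).  Failed replicates become
    NaN; more than 20% failures raises.  Identical (data, estimator, seed)
    yields identical output.
    """
    arr = _as_values(values)
    if reps < 2:
        raise ValueError("need at least 2 bootstrap repetitions")
    rng = np.random.default_rng(seed)
    n = arr.size
    out = np.empty(reps, dtype=float)
    n_failed = 0
    for r in range(reps):
        sample = rng.choice(arr, size=n, replace=True)
        try:
            out[r] = float(estimator(sample))
        except (ValueError, ArithmeticError) as exc:
            out[r] = np.nan
            n_failed += 1
            warnings.warn(f"bootstrap replicate {r} failed: {exc}", stacklevel=2)
    if n_failed > MAX_MISSING_FRACTION * reps:
        raise ValueError(
            f"{n_failed}/{reps} bootstrap replicates failed (> {MAX_MISSING_FRACTION:.0%})"
        )
    return out


def _clean(replicates) -> np.ndarray:
    rep = np.asarray(replicates, dtype=float)
    return rep[~np.isnan(rep)]


def ci_normal(replicates, level: float = 0.95, estimator_name: str = "") -> BootstrapCI:
    """Normal-approximation interval: mean +/- z((1+level)/2) * sample SD."""
    rep = _clean(replicates)
    if rep.size < 2:
        raise ValueError("need at least 2 non-missing replicates")
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    mean = float(np.mean(rep))
    sd = float(np.std(rep, ddof=1))
    z = float(stats.norm.ppf((1 + level) / 2))
    return BootstrapCI(
        estimator_name=estimator_name,
        point_estimate=mean,
        replicate_estimates=np.asarray(replicates, dtype=float),
        n_reps=rep.size,
        level=level,
        flavor="normal",
        lower=mean - z * sd,
        upper=mean + z * sd,
    )


def ci_percentile(replicates, level: float = 0.95, estimator_name: str = "") -> BootstrapCI:
    """Percentile interval: empirical (1-level)/2 and (1+level)/2 quantiles."""
    rep = _clean(replicates)
    if rep.size < 20:
        raise ValueError("need at least 20 non-missing replicates for the percentile method")
    if rep.size < 100:
        warnings.warn(
            "fewer than 100 replicates; percentile CI endpoints are noisy", stacklevel=2
        )
    if not 0 <= level < 1:
        raise ValueError("level must lie in [0, 1)")
    alpha = (1 - level) / 2
    lower, upper = np.percentile(rep, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        estimator_name=estimator_name,
        point_estimate=float(np.median(rep)),
        replicate_estimates=np.asarray(replicates, dtype=float),
        n_reps=rep.size,
        level=level,
        flavor="percentile",
        lower=float(lower),
        upper=float(upper),
    )


def bootstrap_ci(
    values,
    estimator: Callable[[np.ndarray], float],
    reps: int = 500,
    seed: Optional[int] = None,
    level: float = 0.95,
    flavor: Optional[str] = None,
    estimator_name: str = "",
) -> BootstrapCI:
    """End-to-end bootstrap: resample, re-estimate, build the interval.

    ``flavor=None`` picks ``normal`` for reps <= 30 (few, hand-checked
    replicates) and ``percentile`` otherwise.
    """
    replicates = bootstrap_estimates(values, estimator, reps=reps, seed=seed)
    if flavor is None:
        flavor = "normal" if reps <= 30 else "percentile"
    if flavor == "normal":
        ci = ci_normal(replicates, level=level, estimator_name=estimator_name)
    elif flavor == "percentile":
        ci = ci_percentile(replicates, level=level, estimator_name=estimator_name)
    else:
        raise ValueError(f"unknown CI flavor {flavor!r}; use 'normal' or 'percentile'")
    ci.point_estimate = float(estimator(_as_values(values)))
    return ci
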