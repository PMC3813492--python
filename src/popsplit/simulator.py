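"""Bimodal mixture simulation benchmark with known ground truth.

A simulated population mixes a large "OFF" component and a small "ON"
component, both normal.  The default large-component parameters
(mean 63, SD 3.9 AGV units) are typical of non-induced stationary-phase
reporter populations measured by epifluorescence microscopy; small-component
grids span SD 10-50, mean 65-200 and proportions 0.1-40% (or 0.1-1.2% for
the very-small-subpopulation sweep), with total sizes of 2000, 20000 or
200000 cells.

Each splitter's estimate is scored against the known truth with the signed
accuracy metric ``100 * (estimated - true) / true`` (percent): negative
means underestimation, -100 means the method detected nothing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .splitters import split_boxplot, split_default

__all__ = [
    "MixtureSpec",
    "GridSpec",
    "AccuracyRecord",
    "TABLE2_LARGE",
    "TABLE2_SMALL",
    "simulate_mixture",
    "accuracy",
    "run_grid",
    "run_truth_sweep",
]

# Reference mixture parameters (AGV units): large OFF component as measured
# in non-induced populations; small ON component as measured in induced ones.
TABLE2_LARGE = (63.0, 3.9)
TABLE2_SMALL = (127.3, 37.7)


@dataclass(frozen=True)
class MixtureSpec:
    """Parameters of one simulated bimodal population."""

    n_total: int
    large_mean: float = TABLE2_LARGE[0]
    large_sd: float = TABLE2_LARGE[1]
    small_mean: float = TABLE2_SMALL[0]
    small_sd: float = TABLE2_SMALL[1]
    small_pct_true: float = 3.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_total < 100:
            raise ValueError("n_total must be at least 100")
        if self.large_sd <= 0 or self.small_sd <= 0:
            raise ValueError("standard deviations must be positive")
        if not 0 <= self.small_pct_true < 100:
            raise ValueError("small_pct_true must lie in [0, 100)")

    @property
    def n_small(self) -> int:
        """Cell count of the small component: round(pct/100 * n_total)."""
        return int(round(self.small_pct_true / 100.0 * self.n_total))

    @property
    def n_large(self) -> int:
        return self.n_total - self.n_small


@dataclass(frozen=True)
class GridSpec:
    """Cartesian sweep over small-component SD, mean and proportion."""

    sd_range: Tuple[float, float] = (10.0, 50.0)
    mean_range: Tuple[float, float] = (65.0, 200.0)
    pct_range: Tuple[float, float] = (0.1, 40.0)
    n_points: Tuple[int, int, int] = (40, 40, 40)
    n_total: int = 2000
    large_mean: float = TABLE2_LARGE[0]
    large_sd: float = TABLE2_LARGE[1]
    seed: int = 0

    def __post_init__(self) -> None:
        for lo_hi, npts in zip((self.sd_range, self.mean_range, self.pct_range), self.n_points):
            if not lo_hi[0] < lo_hi[1]:
                raise ValueError(f"range must have lo < hi, got {lo_hi}")
            if npts < 2:
                raise ValueError("each grid axis needs at least 2 points")
        if self.pct_range[0] <= 0:
            raise ValueError("proportions must be strictly positive (accuracy undefined at 0)")

    def axes(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Equidistant grid values, inclusive of both endpoints."""
        return (
            np.linspace(*self.sd_range, self.n_points[0]),
            np.linspace(*self.mean_range, self.n_points[1]),
            np.linspace(*self.pct_range, self.n_points[2]),
        )

    @property
    def size(self) -> int:
        return int(np.prod(self.n_points))


@dataclass(frozen=True)
class AccuracyRecord:
    spec: MixtureSpec
    method: str
    small_pct_est: Optional[float]
    accuracy_pct: Optional[float]
    detected: bool


def simulate_mixture(spec: MixtureSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Draw one bimodal population.

    Returns ``(values, labels)`` where ``labels`` is True for cells of the
    small component.  ``round(small_pct_true/100 * n_total)`` cells come
    from Normal(small_mean, small_sd), the rest from
    Normal(large_mean, large_sd).  Identical spec (including seed) gives
    identical draws.
    """
    if spec.small_pct_true > 0 and spec.n_small == 0:
        warnings.warn("subpopulation rounds to zero cells", stacklevel=2)
    rng = np.random.default_rng(spec.seed)
    large = rng.normal(spec.large_mean, spec.large_sd, size=spec.n_large)
    small = rng.normal(spec.small_mean, spec.small_sd, size=spec.n_small)
    values = np.concatenate([large, small])
    labels = np.concatenate(
        [np.zeros(spec.n_large, dtype=bool), np.ones(spec.n_small, dtype=bool)]
    )
    return values, labels


def accuracy(est_pct: float, true_pct: float) -> float:
    """Signed percent accuracy: 100 * (est - true) / true.

    Negative values are underestimates, positive overestimates, 0 exact;
    an estimate of 0 maps to exactly -100 (nothing detected).
    """
    if true_pct <= 0:
        raise ValueError("accuracy undefined for true_pct <= 0")
    return 100.0 * (est_pct - true_pct) / true_pct


_GRID_METHODS = {"boxplot1.5", "boxplot3", "default"}


def _apply_method(values: np.ndarray, method: str, p_conf: float = 0.995) -> float:
    if method == "boxplot1.5":
        return split_boxplot(values, k=1.5).small_pct
    if method == "boxplot3":
        return split_boxplot(values, k=3.0).small_pct
    if method == "default":
        return split_default(values, region="auto", p_conf=p_conf).small_pct
    raise ValueError(f"method {method!r} not usable in batch mode; valid: {sorted(_GRID_METHODS)}")


def _cell_seed(grid_seed: int, index: int) -> int:
    """Deterministic, well-separated per-cell seed below 2**31."""
    ss = np.random.SeedSequence([int(grid_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(grid: GridSpec, method: str, p_conf: float = 0.995) -> pd.DataFrame:
    """Score one automatic splitter over the full parameter grid.

    Returns a long-format DataFrame with one row per grid cell: the mixture
    parameters, the estimate, the signed accuracy, and a ``detected`` flag
    (False when the estimate is 0 or the splitter failed; a failed cell has
    missing estimate/accuracy, mirroring the NA convention).
    """
    if method not in _GRID_METHODS:
        raise ValueError(f"method {method!r} is not automatic; valid: {sorted(_GRID_METHODS)}")
    sds, means, pcts = grid.axes()
    rows = []
    for idx, (sd, mean, pct) in enumerate(itertools.product(sds, means, pcts)):
        spec = MixtureSpec(
            n_total=grid.n_total,
            large_mean=grid.large_mean,
            large_sd=grid.large_sd,
            small_mean=float(mean),
            small_sd=float(sd),
            small_pct_true=float(pct),
            seed=_cell_seed(grid.seed, idx),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            values, _ = simulate_mixture(spec)
        try:
            est = _apply_method(values, method, p_conf=p_conf)
        except ValueError:
            est, acc, detected = np.nan, np.nan, False
        else:
            acc = accuracy(est, pct)
            detected = est > 0
        rows.append(
            {
                "cell_index": idx,
                "method": method,
                "n_total": grid.n_total,
                "large_mean": grid.large_mean,
                "large_sd": grid.large_sd,
                "small_mean": float(mean),
                "small_sd": float(sd),
                "small_pct_true": float(pct),
                "seed": spec.seed,
                "small_pct_est": est,
                "accuracy_pct": acc,
                "detected": detected,
            }
        )
    return pd.DataFrame(rows)


def run_truth_sweep(
    truths: Sequence[float],
    reps: int = 3,
    methods: Iterable[str] = ("boxplot1.5", "boxplot3"),
    n_total: int = 2000,
    large: Tuple[float, float] = TABLE2_LARGE,
    small: Tuple[float, float] = TABLE2_SMALL,
    seed: int = 0,
    p_conf: float = 0.995,
) -> pd.DataFrame:
    """Estimated-vs-true summary over a list of true proportions.

    For every truth and method, ``reps`` independent populations are
    simulated and the estimates summarized as mean +/- SD (the reference
    layout uses 3 independent repetitions at N=2000 with large component
    Normal(63, 3.9) and small component Normal(127.3, 37.7)).
    """
    if reps < 2:
        raise ValueError("need at least 2 repetitions")
    methods = list(methods)
    for m in methods:
        if m not in _GRID_METHODS:
            raise ValueError(f"method {m!r} is not automatic; valid: {sorted(_GRID_METHODS)}")
    rows = []
    for t_idx, truth in enumerate(truths):
        if truth <= 0:
            raise ValueError("true proportions must be strictly positive")
        specs = [
            MixtureSpec(
                n_total=n_total,
                large_mean=large[0],
                large_sd=large[1],
                small_mean=small[0],
                small_sd=small[1],
                small_pct_true=float(truth),
                seed=_cell_seed(seed, t_idx * reps + r),
            )
            for r in range(reps)
        ]
        draws = [simulate_mixture(s)[0] for s in specs]
        for method in methods:
            ests = []
            for values in draws:
                try:
                    ests.append(_apply_method(values, method, p_conf=p_conf))
                except ValueError:
                    ests.append(np.nan)
            ests = np.asarray(ests, dtype=float)
            ok = ests[~np.isnan(ests)]
            rows.append(
                {
                    "small_pct_true": float(truth),
                    "method": method,
                    "reps": reps,
                    "n_failed": int(np.isnan(ests).sum()),
                    "est_mean": float(np.mean(ok)) if ok.size else np.nan,
                    "est_sd": float(np.std(ok, ddof=1)) if ok.size > 1 else np.nan,
                    "accuracy_mean": accuracy(float(np.mean(ok)), truth) if ok.size else np.nan,
                }
            )
    return pd.DataFrame(rows)
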