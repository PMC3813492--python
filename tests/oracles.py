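"""Independent closed-form oracles for the simulation benchmark.

These deliberately avoid the package's code paths: quantiles of the
two-component normal mixture are obtained by root-finding on the exact
mixture CDF, and the expected splitter estimate is the exact upper-tail
mass of the mixture beyond the resulting fence.  Empirical estimates at
large N must agree with these values within binomial sampling error.
"""

from __future__ import annotations

from scipy.optimize import brentq
from scipy.stats import norm


def mixture_cdf(x, w_small, large_mean, large_sd, small_mean, small_sd):
    return (1 - w_small) * norm.cdf(x, large_mean, large_sd) + w_small * norm.cdf(
        x, small_mean, small_sd
    )


def mixture_quantile(p, w_small, large_mean, large_sd, small_mean, small_sd):
    lo = min(large_mean - 10 * large_sd, small_mean - 10 * small_sd)
    hi = max(large_mean + 10 * large_sd, small_mean + 10 * small_sd)
    return brentq(
        lambda x: mixture_cdf(x, w_small, large_mean, large_sd, small_mean, small_sd) - p,
        lo,
        hi,
    )


def expected_boxplot_estimate(
    k, small_pct_true, large_mean=63.0, large_sd=3.9, small_mean=127.3, small_sd=37.7
):
    """Population value of the boxplot split: tail mass beyond Q3 + k*IQR (%)."""
    w = small_pct_true / 100.0
    args = (w, large_mean, large_sd, small_mean, small_sd)
    q1 = mixture_quantile(0.25, *args)
    q3 = mixture_quantile(0.75, *args)
    fence = q3 + k * (q3 - q1)
    return 100.0 * (1.0 - mixture_cdf(fence, *args))
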