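"""Power of the discordant-pair design at epigenome-wide significance.

The within-pair test is a two-sided one-sample t-test of n normal pair
differences with true mean delta (beta scale) and SD sd_d; its power is
exact under the noncentral-t distribution with df n-1 and noncentrality
delta * sqrt(n) / sd_d.  At epigenome-wide alpha (~1.2e-7) the noncentral-t
form differs materially from the normal approximation, so the t form is used
throughout.  ``calibrate_sd`` inverts the power function to recover the
within-pair SD implied by a stated (n, delta, alpha, power) operating point;
``power_simulation`` is a Monte-Carlo cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

__all__ = ["paired_power", "calibrate_sd", "power_simulation"]


def _validate(n, sd_d, alpha):
    if n < 2:
        raise ValueError("n must be >= 2")
    if sd_d <= 0:
        raise ValueError("sd_d must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")


def paired_power(n: int, delta: float, sd_d: float, alpha: float) -> float:
    """Analytic power of the two-sided paired t-test.

    P(|T'| > t_{1-alpha/2, n-1}) with T' noncentral t, df n-1, noncentrality
    delta * sqrt(n) / sd_d.
    """
    _validate(n, sd_d, alpha)
    df = n - 1
    tc = stats.t.ppf(1.0 - alpha / 2.0, df)
    nc = delta * np.sqrt(n) / sd_d
    # the noncentral-t tail functions can underflow to NaN at extreme
    # noncentrality; fall back per tail on the asymptotic normal bound there
    upper = stats.nct.sf(tc, df, nc)
    if np.isnan(upper):
        upper = stats.norm.sf(tc - nc)
    lower = stats.nct.cdf(-tc, df, nc)
    if np.isnan(lower):
        lower = stats.norm.cdf(-tc - nc)
    return float(min(max(upper + lower, 0.0), 1.0))


def calibrate_sd(
    n: int, delta: float, alpha: float, target_power: float
) -> float:
    """Within-pair difference SD at which the paired t-test hits a power.

    Power is strictly decreasing in sd_d (for delta > 0), so the root is
    unique; found by bracketing + Brent to relative tolerance 1e-8.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not alpha < target_power < 1:
        raise ValueError("target_power must be in (alpha, 1)")
    _validate(n, 1.0, alpha)

    f = lambda sd: paired_power(n, delta, sd, alpha) - target_power
    lo, hi = delta * 1e-3, delta * 1e-3 * 2
    while f(hi) > 0:
        lo, hi = hi, hi * 2.0
        if hi > delta * 1e9:
            raise ValueError("target power unbracketable")
    return float(optimize.brentq(f, lo, hi, rtol=1e-10, xtol=1e-14))


def power_simulation(
    n: int,
    delta: float,
    sd_d: float,
    alpha: float,
    reps: int = 10_000,
    seed: int = 0,
) -> dict:
    """Empirical power by simulation of normal within-pair differences.

    Returns the rejection fraction at ``alpha`` and its binomial Monte-Carlo
    standard error.  Seeded and vectorized.
    """
    _validate(n, sd_d, alpha)
    if reps < 1000:
        raise ValueError("reps must be >= 1000")
    rng = np.random.default_rng(seed)
    d = rng.normal(delta, sd_d, size=(reps, n))
    t = d.mean(axis=1) / (d.std(axis=1, ddof=1) / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    rej = float((p < alpha).mean())
    return {
        "power": rej,
        "se": float(np.sqrt(max(rej * (1 - rej), 1.0 / reps) / reps)),
        "reps": reps,
        "seed": seed,
    }
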