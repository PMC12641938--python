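"""Moment-matched truncated samplers used by the synthetic-data generator.

The study publishes group parameters as mean +/- SD, but several of the
quantities live on bounded supports (dwell durations inside the detector's
80-420 ms window, angles in [0, 180] degrees, fractions in (0, 1)). Naively
truncating a normal at those bounds shifts its mean, which would silently
bias every recovery experiment. The samplers here instead solve for the
location (or log-scale) parameter so that the *truncated* distribution has
exactly the requested mean; the requested SD is interpreted as the spread
parameter of the parent distribution.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps
from scipy.optimize import brentq

__all__ = [
    "truncated_normal_mean_matched",
    "truncated_lognormal_mean_matched",
    "lognormal_mu_for_truncated_mean",
    "sample_truncated_lognormal",
]

_NORM = sps.norm


def _truncnorm_mean(loc: float, scale: float, lo: float, hi: float) -> float:
    a = (lo - loc) / scale
    b = (hi - loc) / scale
    return float(sps.truncnorm.mean(a, b, loc=loc, scale=scale))


def truncated_normal_mean_matched(target_mean, sd, lo, hi, rng, size=None):
    """Sample a normal truncated to [lo, hi] whose mean equals target_mean.

    The location parameter is solved with Brent's method; `sd` is the parent
    (pre-truncation) standard deviation. `target_mean` must lie strictly
    inside (lo, hi). With sd == 0 the draw is the constant target.
    """
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} not inside ({lo}, {hi})")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return (
            float(target_mean)
            if size is None
            else np.full(size, float(target_mean))
        )
    loc = brentq(
        lambda c: _truncnorm_mean(c, sd, lo, hi) - target_mean,
        target_mean - 12 * sd,
        target_mean + 12 * sd,
        xtol=1e-12,
    )
    a = (lo - loc) / sd
    b = (hi - loc) / sd
    u = rng.uniform(_NORM.cdf(a), _NORM.cdf(b), size=size)
    out = loc + sd * _NORM.ppf(u)
    return np.clip(out, lo, hi)  # guard fp round-off at the edges


def _phi_diff(a: float, b: float) -> float:
    """Phi(b) - Phi(a) for b >= a, stable in both tails."""
    if a > 0:
        return float(_NORM.sf(a) - _NORM.sf(b))
    return float(_NORM.cdf(b) - _NORM.cdf(a))


def _trunc_lognorm_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    # E[X | lo < X < hi] for X ~ LogNormal(mu, sigma), closed form
    llo, lhi = math.log(lo), math.log(hi)
    z = _phi_diff((llo - mu) / sigma, (lhi - mu) / sigma)
    num = _phi_diff((llo - mu - sigma**2) / sigma, (lhi - mu - sigma**2) / sigma)
    if z <= 0.0 or num <= 0.0:  # support collapsed numerically onto a bound
        return lo if mu < (llo + lhi) / 2 else hi
    return math.exp(mu + sigma**2 / 2) * num / z


def lognormal_mu_for_truncated_mean(target_mean, shape, lo, hi) -> float:
    """Log-location mu such that LogNormal(mu, shape)|[lo, hi] has the target mean."""
    if not lo < target_mean < hi:
        raise ValueError(f"target mean {target_mean} not inside ({lo}, {hi})")
    if shape <= 0:
        raise ValueError("shape must be > 0")

    def f(m: float) -> float:
        return _trunc_lognorm_mean(m, shape, lo, hi) - target_mean

    # expand the bracket from log(target) until it straddles the root
    a = b = math.log(target_mean)
    step = shape
    for _ in range(80):
        if f(a) < 0:
            break
        a -= step
        step *= 2
    step = shape
    for _ in range(80):
        if f(b) > 0:
            break
        b += step
        step *= 2
    return brentq(f, a, b, xtol=1e-12)


def sample_truncated_lognormal(mu, shape, lo, hi, rng, size=None):
    """Inverse-CDF draw from LogNormal(mu, shape) truncated to [lo, hi]."""
    llo = _NORM.cdf((math.log(lo) - mu) / shape)
    lhi = _NORM.cdf((math.log(hi) - mu) / shape)
    u = rng.uniform(llo, lhi, size=size)
    out = np.exp(mu + shape * _NORM.ppf(u))
    return np.clip(out, lo, hi)


def truncated_lognormal_mean_matched(target_mean, shape, lo, hi, rng, size=None):
    """Sample a log-normal truncated to [lo, hi] with mean target_mean.

    `shape` is the log-scale sigma (controls right-skew); the log-location
    mu is solved so the truncated mean hits the target. Suits dwell
    durations: positive, right-skewed, bounded by the detector's window.
    """
    mu = lognormal_mu_for_truncated_mean(target_mean, shape, lo, hi)
    return sample_truncated_lognormal(mu, shape, lo, hi, rng, size=size)
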