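"""Discrete power-law fitting for degree distributions.

Scale-free networks have degree distributions p(x) ~ x^-alpha.  The fit
here is the standard maximum-likelihood procedure for discrete data: for
each candidate lower cutoff xmin, the exponent is estimated by maximizing
the Hurwitz-zeta likelihood

    L(alpha) = -alpha * sum(log x_i) - n * log zeta(alpha, xmin)

over the tail x >= xmin, and xmin is chosen to minimize the
Kolmogorov-Smirnov distance between the empirical tail CDF and the fitted
one.  A log-log regression slope of the degree histogram is reported
alongside, since network "slope" comparisons are often phrased that way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta

from .errors import ParameterError, SupportError

_ALPHA_LO, _ALPHA_HI = 1.01, 8.0


@dataclass
class PowerLawFit:
    """MLE fit of a discrete power-law tail p(x) ~ x^-alpha, x >= xmin."""

    alpha: float
    xmin: int
    ks_distance: float
    n_tail: int
    loglog_slope: float | None = None

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ParameterError("power-law exponent must exceed 1")
        if self.xmin < 1:
            raise ParameterError("xmin must be >= 1")


def _mle_alpha(tail: np.ndarray, xmin: int) -> float:
    slogx = float(np.log(tail).sum())
    n = len(tail)

    def nll(alpha: float) -> float:
        return alpha * slogx + n * np.log(zeta(alpha, xmin))

    res = minimize_scalar(nll, bounds=(_ALPHA_LO, _ALPHA_HI), method="bounded")
    return float(res.x)


def _ks_distance(tail: np.ndarray, alpha: float, xmin: int) -> float:
    xs = np.arange(xmin, tail.max() + 1)
    pmf = xs ** (-alpha) / zeta(alpha, xmin)
    cdf_fit = np.cumsum(pmf)
    # empirical CDF evaluated at the same support points
    sorted_tail = np.sort(tail)
    ecdf = np.searchsorted(sorted_tail, xs, side="right") / len(tail)
    return float(np.abs(ecdf - cdf_fit).max())


def fit_power_law(
    degrees: np.ndarray, min_tail: int = 10, max_xmin_candidates: int = 50
) -> PowerLawFit:
    """Fit a discrete power law to positive integer degrees.

    Zero degrees are dropped.  Every distinct degree value (capped at
    ``max_xmin_candidates``, tails below ``min_tail`` skipped) is tried as
    xmin; the KS-minimizing cutoff wins.  Fewer than 50 nonzero degrees
    triggers a stability warning; an all-equal sequence is degenerate and
    raises.
    """
    degrees = np.asarray(degrees)
    if not np.issubdtype(degrees.dtype, np.integer):
        if not np.allclose(degrees, np.round(degrees)):
            raise ParameterError("degrees must be integers")
        degrees = np.round(degrees).astype(int)
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        raise SupportError("no nonzero degrees")
    if degrees.size < 50:
        warnings.warn(
            f"only {degrees.size} nonzero degrees; power-law fit may be unstable"
        )
    if np.unique(degrees).size == 1:
        raise ParameterError("all degrees equal; power-law fit is degenerate")

    candidates = np.unique(degrees)[:max_xmin_candidates]
    best = None
    for xmin in candidates:
        tail = degrees[degrees >= xmin]
        if tail.size < min_tail or np.unique(tail).size == 1:
            continue
        alpha = _mle_alpha(tail, int(xmin))
        ks = _ks_distance(tail, alpha, int(xmin))
        if best is None or ks < best[0]:
            best = (ks, alpha, int(xmin), tail.size)
    if best is None:  # tiny sample: fall back to xmin = min degree
        xmin = int(candidates[0])
        tail = degrees[degrees >= xmin]
        alpha = _mle_alpha(tail, xmin)
        best = (_ks_distance(tail, alpha, xmin), alpha, xmin, tail.size)

    ks, alpha, xmin, n_tail = best
    return PowerLawFit(
        alpha=alpha,
        xmin=xmin,
        ks_distance=ks,
        n_tail=n_tail,
        loglog_slope=_loglog_slope(degrees),
    )


def _loglog_slope(degrees: np.ndarray) -> float | None:
    """Least-squares slope of log frequency vs log degree (descriptive only)."""
    vals, counts = np.unique(degrees, return_counts=True)
    if len(vals) < 3:
        return None
    lx, ly = np.log(vals.astype(float)), np.log(counts.astype(float))
    return float(np.polyfit(lx, ly, 1)[0])


def sample_discrete_power_law(
    alpha: float,
    xmin: int,
    size: int,
    rng: np.random.Generator,
    xmax: int = 100_000,
) -> np.ndarray:
    """Inverse-CDF sampling from p(x) ~ x^-alpha on {xmin, ..., xmax}."""
    if alpha <= 1:
        raise ParameterError("alpha must exceed 1")
    xs = np.arange(xmin, xmax + 1, dtype=float)
    pmf = xs ** (-alpha)
    pmf /= pmf.sum()
    cdf = np.cumsum(pmf)
    u = rng.random(size)
    return xs[np.searchsorted(cdf, u)].astype(int)
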