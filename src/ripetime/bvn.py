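"""Bivariate normal CDF and rectangle probabilities.

The interval-censored likelihood needs P(X in [a1,b1] x [a2,b2]) for a
bivariate normal X, evaluated deterministically and to machine precision so
that the quadrature-based log-likelihood is smooth enough for quasi-Newton
optimisation.  The standard-normal joint CDF is computed from Owen's T
function (Owen 1956), which reduces the bivariate orthant problem to a single
special-function call; the rectangle then follows by inclusion-exclusion over
the four corners.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, owens_t

# beyond |x| = 39 the univariate normal CDF is exactly 0 or 1 in double
# precision, so infinities can be clipped there without loss
_CLIP = 39.0


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF ``P(X <= h, Y <= k)`` with correlation rho.

    Vectorised over ``h`` and ``k``; ``rho`` is scalar in (-1, 1) (the
    degenerate limits +-1 are handled exactly).  Infinite bounds are allowed.
    """
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    h, k = np.broadcast_arrays(h, k)
    rho = float(rho)
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {rho}")
    if rho == 1.0:
        return ndtr(np.minimum(h, k))
    if rho == -1.0:
        return np.maximum(ndtr(h) + ndtr(k) - 1.0, 0.0)

    r = np.sqrt((1.0 - rho) * (1.0 + rho))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        a_h = (k - rho * h) / (h * r)
        a_k = (h - rho * k) / (k * r)
    # Owen's T at zero first argument: T(0, a) = arctan(a) / (2 pi); the
    # division above degenerates there, so patch the limit in by hand
    zero_h = h == 0.0
    zero_k = k == 0.0
    t_h = owens_t(np.where(zero_h, 1.0, h), np.where(zero_h, 0.0, a_h))
    t_k = owens_t(np.where(zero_k, 1.0, k), np.where(zero_k, 0.0, a_k))
    t_h = np.where(zero_h, np.sign(k) * 0.25, t_h)
    t_k = np.where(zero_k, np.sign(h) * 0.25, t_k)

    # branch constant of Owen's decomposition; sign logic rather than the
    # product h*k, which can underflow to zero for tiny arguments
    opposite = ((h > 0) & (k < 0)) | ((h < 0) & (k > 0))
    beta = np.where(opposite | ((zero_h | zero_k) & (h + k < 0)), 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - t_h - t_k - beta
    # both arguments zero: closed form 1/4 + arcsin(rho) / (2 pi)
    both_zero = zero_h & zero_k
    if np.any(both_zero):
        out = np.where(both_zero, 0.25 + np.arcsin(rho) / (2.0 * np.pi), out)
    return np.clip(out, 0.0, 1.0)


def _check_cov(cov: np.ndarray) -> tuple[float, float, float]:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise ValueError("covariance must be 2x2")
    if not np.allclose(cov, cov.T):
        raise ValueError("covariance must be symmetric")
    s1 = cov[0, 0]
    s2 = cov[1, 1]
    det = s1 * s2 - cov[0, 1] ** 2
    if s1 <= 0 or s2 <= 0 or det <= 0:
        raise ValueError(f"covariance is not positive definite: {cov.tolist()}")
    return np.sqrt(s1), np.sqrt(s2), cov[0, 1] / np.sqrt(s1 * s2)


def standardized_rectangle_probability(a1, b1, a2, b2, rho):
    """P(a1 <= X <= b1, a2 <= Y <= b2) for standard bivariate normal (X, Y).

    Inclusion-exclusion over the four corners of the rectangle; vectorised
    over the bounds.  Values are clipped to [0, 1] to absorb round-off.
    """
    p = (
        bvn_cdf(b1, b2, rho)
        - bvn_cdf(a1, b2, rho)
        - bvn_cdf(b1, a2, rho)
        + bvn_cdf(a1, a2, rho)
    )
    return np.clip(p, 0.0, 1.0)


def mvn_rectangle_probability(mean, cov, rect) -> float:
    """Probability that a bivariate normal falls in an axis-aligned rectangle.

    Parameters
    ----------
    mean : array-like, shape (2,)
    cov : array-like, shape (2, 2)
        Positive definite covariance matrix.
    rect : ((lower1, lower2), (upper1, upper2))
        Rectangle bounds; ``+-inf`` entries are allowed.
    """
    mean = np.asarray(mean, dtype=float)
    s1, s2, rho = _check_cov(cov)
    (l1, l2), (u1, u2) = rect
    if l1 > u1 or l2 > u2:
        raise ValueError("rectangle lower bounds must not exceed upper bounds")
    with np.errstate(invalid="ignore"):
        a1 = (l1 - mean[0]) / s1
        b1 = (u1 - mean[0]) / s1
        a2 = (l2 - mean[1]) / s2
        b2 = (u2 - mean[1]) / s2
    return float(standardized_rectangle_probability(a1, b1, a2, b2, rho))
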