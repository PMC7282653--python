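"""The Cauchy-like null distribution of the retention-fraction estimate.

With the treatment-vs-control difference estimate distributed
``N(mu_NI, sigma_NI^2)`` and the historical control-vs-placebo difference
estimate ``N(mu_H, sigma_H^2)``, the observed retention fraction

    z_hat = 1 - (C_NI - T_NI)_hat / (C_H - P_H)_hat

is distributed as ``r*(a + X)/(b + Y) + 1`` for independent standard normals
X, Y, where

    a = -mu_NI / sigma_NI      (standardized treatment-vs-control difference)
    b = mu_H / sigma_H         (standardized historical control effect)
    r = sigma_NI / sigma_H

This is Marsaglia's ratio-of-normals law after a linear transformation: a
heavy-tailed, generally asymmetric distribution that reduces to a shifted,
scaled Cauchy when a = b = 0.  This module provides a numerically exact CDF,
density, quantile function and a sampler; the ratio test rejects the
fraction-retention null when z_hat falls in the upper tail.

The CDF is obtained by one-dimensional quadrature over the denominator
variable: conditioning on Y = y,

    P((a+X)/(b+y) <= t) = Phi(t(b+y) - a)        if b + y > 0
                        = 1 - Phi(t(b+y) - a)    if b + y < 0,

and the two sign regions are integrated against the standard normal density
of y separately.  The integral is truncated at |y| <= 12 (normal mass beyond
is ~1.8e-33, negligible against the 1e-8 accuracy contract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy.optimize import brentq
from scipy.special import ndtr

from .exceptions import InvalidParameterError

__all__ = [
    "RatioNormalParams",
    "NullBoundaryParams",
    "ratio_normal_cdf",
    "ratio_normal_pdf",
    "cauchy_like_cdf",
    "cauchy_like_pdf",
    "cauchy_like_quantile",
    "sample_cauchy_like",
]

# Standard-normal mass beyond +/-12 is ~1.8e-33; irrelevant at 1e-8 accuracy.
_Y_CUT = 12.0
_EPSABS = 1e-11
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


def _phi(y: float) -> float:
    return _INV_SQRT_2PI * math.exp(-0.5 * y * y)


@dataclass(frozen=True)
class RatioNormalParams:
    """Parameters (a, b, r) of the law ``r*(a+X)/(b+Y) + 1``.

    a : standardized treatment-vs-control difference, ``-mu_NI/sigma_NI``
    b : standardized historical control effect, ``mu_H/sigma_H``
    r : SD ratio ``sigma_NI/sigma_H`` (> 0)
    """

    a: float
    b: float
    r: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "r"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        if self.r <= 0:
            raise InvalidParameterError(f"r must be > 0, got {self.r}")


@dataclass(frozen=True)
class NullBoundaryParams:
    """The null-boundary parameterization G_{b,r,delta0}.

    On the boundary of the fraction-retention null (true retention equal to
    delta0) the treatment-vs-control mean is ``mu_NI = mu_H*(1 - delta0)``,
    which pins the numerator offset to ``a = -(1 - delta0)*b/r``.
    """

    b: float
    r: float
    delta0: float

    def __post_init__(self) -> None:
        for name in ("b", "r", "delta0"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        if self.r <= 0:
            raise InvalidParameterError(f"r must be > 0, got {self.r}")

    @property
    def a(self) -> float:
        return -(1.0 - self.delta0) * self.b / self.r


def ratio_normal_cdf(t: float, a: float, b: float) -> float:
    """P((a+X)/(b+Y) <= t) for independent standard normals X, Y.

    ``t`` may be ``+/-inf``; absolute accuracy is at least 1e-8.
    """
    if not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidParameterError("a and b must be finite")
    if math.isnan(t):
        raise InvalidParameterError("t must be a number or +/-inf")
    if t == math.inf:
        return 1.0
    if t == -math.inf:
        return 0.0

    def f_pos(y: float) -> float:  # region b + y > 0
        return _phi(y) * ndtr(t * (b + y) - a)

    def f_neg(y: float) -> float:  # region b + y < 0
        return _phi(y) * ndtr(a - t * (b + y))

    split = -b
    total = 0.0
    if split > -_Y_CUT:
        hi = min(split, _Y_CUT)
        total += integrate.quad(f_neg, -_Y_CUT, hi, epsabs=_EPSABS, limit=300)[0]
    if split < _Y_CUT:
        lo = max(split, -_Y_CUT)
        total += integrate.quad(f_pos, lo, _Y_CUT, epsabs=_EPSABS, limit=300)[0]
    # clip quadrature round-off into [0, 1]
    return min(1.0, max(0.0, total))


def ratio_normal_pdf(t: float, a: float, b: float) -> float:
    """Density of (a+X)/(b+Y) at t: integral of |b+y| phi(t(b+y)-a) phi(y)."""
    if not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidParameterError("a and b must be finite")
    if not math.isfinite(t):
        return 0.0

    def f(y: float) -> float:
        return abs(b + y) * _phi(t * (b + y) - a) * _phi(y)

    split = -b
    total = 0.0
    if split > -_Y_CUT:
        total += integrate.quad(f, -_Y_CUT, min(split, _Y_CUT), epsabs=_EPSABS, limit=300)[0]
    if split < _Y_CUT:
        total += integrate.quad(f, max(split, -_Y_CUT), _Y_CUT, epsabs=_EPSABS, limit=300)[0]
    return total


def cauchy_like_cdf(z: float, params: NullBoundaryParams) -> float:
    """G_{b,r,delta0}(z): CDF of ``r*(a+X)/(b+Y) + 1`` at the null boundary."""
    if math.isnan(z):
        raise InvalidParameterError("z must be a number or +/-inf")
    if z == math.inf:
        return 1.0
    if z == -math.inf:
        return 0.0
    return ratio_normal_cdf((z - 1.0) / params.r, params.a, params.b)


def cauchy_like_pdf(z: float, params: NullBoundaryParams) -> float:
    """Density of G_{b,r,delta0} at z."""
    return ratio_normal_pdf((z - 1.0) / params.r, params.a, params.b) / params.r


def cauchy_like_quantile(p: float, params: NullBoundaryParams) -> float:
    """Quantile function G_{b,r,delta0}^{-1}(p) for 0 < p < 1.

    Brackets the root geometrically before refining with Brent's method: the
    Cauchy-type tails are too heavy for any fixed bracket to be safe.
    """
    if not (0.0 < p < 1.0):
        raise InvalidParameterError(f"p must be in (0, 1), got {p}")
    half = 50.0 * params.r * (1.0 + abs(params.a)) / (1.0 + abs(params.b))
    lo, hi = 1.0 - half, 1.0 + half
    while cauchy_like_cdf(lo, params) > p:
        lo = 1.0 - 4.0 * (1.0 - lo)
    while cauchy_like_cdf(hi, params) < p:
        hi = 1.0 + 4.0 * (hi - 1.0)
    return brentq(lambda z: cauchy_like_cdf(z, params) - p, lo, hi, xtol=1e-12)


def sample_cauchy_like(n: int, params: NullBoundaryParams, seed) -> np.ndarray:
    """n independent draws of ``r*(a+X)/(b+Y) + 1`` at the null boundary.

    A denominator of exactly zero (a probability-zero event) yields ``+/-inf``,
    which is kept; reproducible under a fixed seed.
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    y = rng.standard_normal(n)
    with np.errstate(divide="ignore"):
        return params.r * (params.a + x) / (params.b + y) + 1.0
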