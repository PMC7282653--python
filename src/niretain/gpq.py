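"""Generalized-p-value (GPV) test of the fraction-retention hypothesis.

Given raw observations X_H (historical arm effect scale, mean mu_H) and Y_NI
(NI-trial difference scale, mean mu_NI), both normal with unknown variances,
the retention hypothesis delta > delta0 is equivalent to

    H0: mu_NI/mu_H >= 1 - delta0   vs   H1: mu_NI/mu_H < 1 - delta0.

A generalized pivotal quantity (GPQ) for a normal mean is

    R_mu = xbar - Z * sqrt((n-1) s^2 / (n U)),

with Z ~ N(0,1), U ~ chi^2(n-1) independent: its distribution is free of
(mu, sigma^2) given the data, and its observed value is mu.  The GPQ for the
ratio mu_NI/mu_H is the elementwise ratio R_muNI / R_muH built from four
mutually independent random streams.  The generalized p-value is the Monte
Carlo frequency with which the ratio GPQ lands at or above the null boundary
1 - delta0; H0 is rejected when that frequency falls below alpha.

Ties at the boundary count toward the tail (conservative), and infinite
ratio draws — the denominator GPQ crossing zero when the historical effect
is weak — are kept, with +inf in the tail and -inf outside it.  The four
streams are spawned deterministically from one user seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .exceptions import InsufficientDataError, InvalidParameterError
from .ni_tests import TestResult

__all__ = [
    "ArmStats",
    "ArmSamples",
    "GpqDraws",
    "summarize",
    "sample_gpq_mu",
    "sample_gpq_ratio",
    "gpv_pvalue",
    "gpv_test",
]

SeedLike = Union[int, np.random.SeedSequence]


@dataclass(frozen=True)
class ArmStats:
    """Sufficient statistics of one arm: mean, n-1-divisor variance, size."""

    mean: float
    variance: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"need n >= 2 observations, got {self.n}")
        if not (math.isfinite(self.mean) and math.isfinite(self.variance)):
            raise InvalidParameterError("mean and variance must be finite")
        if self.variance < 0:
            raise InvalidParameterError(f"variance must be >= 0, got {self.variance}")


@dataclass(frozen=True)
class ArmSamples:
    """Raw observations of one arm (length >= 2, all finite)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InsufficientDataError("need at least 2 observations in a 1-d sequence")
        if not np.all(np.isfinite(arr)):
            raise InvalidParameterError("all observations must be finite")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class GpqDraws:
    """Monte Carlo realizations of the ratio GPQ R_{muNI/muH}."""

    ratio_draws: np.ndarray
    M: int
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratio_draws, dtype=float)
        if arr.size != self.M:
            raise InvalidParameterError("ratio_draws length must equal M")
        object.__setattr__(self, "ratio_draws", arr)


def summarize(samples: ArmSamples) -> ArmStats:
    """Mean, sample variance (divisor n-1) and size of one arm."""
    v = samples.values
    return ArmStats(mean=float(v.mean()), variance=float(v.var(ddof=1)), n=v.size)


def _mu_draws(stats: ArmStats, z: np.ndarray, u: np.ndarray) -> np.ndarray:
    # R_mu = xbar - Z sqrt((n-1) s^2 / (n U))
    return stats.mean - z * np.sqrt((stats.n - 1) * stats.variance / (stats.n * u))


def _seed_seq(seed: SeedLike) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)


def sample_gpq_mu(stats: ArmStats, M: int, seed: SeedLike) -> np.ndarray:
    """M independent GPQ draws for one normal mean, from two substreams."""
    if M < 1:
        raise InvalidParameterError(f"M must be >= 1, got {M}")
    ss_z, ss_u = _seed_seq(seed).spawn(2)
    z = np.random.default_rng(ss_z).standard_normal(M)
    u = np.random.default_rng(ss_u).chisquare(stats.n - 1, M)
    return _mu_draws(stats, z, u)


def _ratio_draws(
    stats_h: ArmStats, stats_ni: ArmStats, M: int, ss: np.random.SeedSequence
) -> np.ndarray:
    """Elementwise R_muNI / R_muH from four independent substreams.

    Substream order is (Z_H, Z_NI, U_H, U_NI); zero denominators give inf.
    """
    ss_zh, ss_zni, ss_uh, ss_uni = ss.spawn(4)
    z_h = np.random.default_rng(ss_zh).standard_normal(M)
    z_ni = np.random.default_rng(ss_zni).standard_normal(M)
    u_h = np.random.default_rng(ss_uh).chisquare(stats_h.n - 1, M)
    u_ni = np.random.default_rng(ss_uni).chisquare(stats_ni.n - 1, M)
    r_h = _mu_draws(stats_h, z_h, u_h)
    r_ni = _mu_draws(stats_ni, z_ni, u_ni)
    with np.errstate(divide="ignore", invalid="ignore"):
        return r_ni / r_h


def sample_gpq_ratio(
    stats_h: ArmStats, stats_ni: ArmStats, M: int, seed: SeedLike
) -> GpqDraws:
    """M draws of the ratio GPQ R_{muNI/muH} (four independent streams)."""
    if M < 1:
        raise InvalidParameterError(f"M must be >= 1, got {M}")
    draws = _ratio_draws(stats_h, stats_ni, M, _seed_seq(seed))
    return GpqDraws(ratio_draws=draws, M=M, seed=seed if isinstance(seed, int) else None)


def gpv_pvalue(draws: GpqDraws, delta0: float) -> float:
    """Upper-tail GPQ frequency at the null boundary: P_hat(R >= 1 - delta0).

    Ties count toward the tail; +inf draws count, -inf draws do not.
    """
    return float(np.mean(draws.ratio_draws >= 1.0 - delta0))


def gpv_test(
    samples_h: Union[ArmSamples, ArmStats],
    samples_ni: Union[ArmSamples, ArmStats],
    delta0: float,
    alpha: float = 0.025,
    M: int = 10000,
    seed: SeedLike = 0,
) -> TestResult:
    """Run the GPV test from raw samples or per-arm sufficient statistics.

    Default M = 10000 GPQ draws; the p-value has Monte Carlo standard error
    at most 0.5/sqrt(M).  Fully reproducible under a fixed integer seed.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")
    stats_h = summarize(samples_h) if isinstance(samples_h, ArmSamples) else samples_h
    stats_ni = summarize(samples_ni) if isinstance(samples_ni, ArmSamples) else samples_ni
    draws = sample_gpq_ratio(stats_h, stats_ni, M, seed)
    p = gpv_pvalue(draws, delta0)
    return TestResult(
        method="gpv",
        statistic=None,
        p_value=p,
        delta0=delta0,
        alpha=alpha,
        reject=p < alpha,
        mc_draws=M,
        seed=seed if isinstance(seed, int) else None,
    )
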