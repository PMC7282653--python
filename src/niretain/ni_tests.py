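"""Summary-statistics tests of the fraction-retention non-inferiority hypothesis.

All three tests address

    H0: delta <= delta0   vs   H1: delta > delta0,

where delta = theta1/theta2 is the fraction of the historical control effect
(theta2, control vs placebo) retained by the new treatment (theta1, treatment
vs placebo), under the constancy assumption.  Inputs are the two difference
estimates and their standard deviations:

    mu_ni_hat ~ N(mu_NI, sigma_NI^2)   (control minus treatment, NI trial)
    mu_h_hat  ~ N(mu_H,  sigma_H^2)    (control minus placebo, historical)

* Rothmann's test uses the linearized statistic
  Z_R = [mu_ni_hat - (1-delta0) mu_h_hat] / sqrt(sigma_NI^2 + (1-delta0)^2 sigma_H^2)
  and rejects for small Z_R; we report the lower normal tail as the p-value.
* Wang's test standardizes the observed retention fraction; for a positive
  historical effect estimate it is algebraically the same test as Rothmann's
  (W = -Z_R), reported as an upper normal tail.
* The ratio test evaluates the observed retention fraction
  z_hat = 1 - mu_ni_hat/mu_h_hat directly against its exact Cauchy-like null
  distribution with plug-in (b_hat, r_hat); it makes no positivity or
  homogeneity assumption about the control effect.

Working in p-value space (reject iff p < alpha) removes the critical-value
sign ambiguities between the rejection-region formulations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.special import ndtr

from .exceptions import DegenerateDenominatorError, InvalidParameterError
from .ratio_normal import NullBoundaryParams, cauchy_like_cdf

__all__ = [
    "TrialSummary",
    "TestResult",
    "rothmann_test",
    "wang_test",
    "estimate_b_r",
    "ratio_test",
]


@dataclass(frozen=True)
class TrialSummary:
    """The two difference estimates of a retention NI analysis.

    mu_ni_hat : estimate of C_NI - T_NI (e.g. a log hazard-ratio difference)
    sigma_ni  : its standard deviation (> 0)
    mu_h_hat  : estimate of C_H - P_H from the historical meta-analysis
    sigma_h   : its standard deviation (> 0)
    """

    mu_ni_hat: float
    sigma_ni: float
    mu_h_hat: float
    sigma_h: float

    def __post_init__(self) -> None:
        for name in ("mu_ni_hat", "sigma_ni", "mu_h_hat", "sigma_h"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidParameterError(f"{name} must be finite")
        if self.sigma_ni <= 0 or self.sigma_h <= 0:
            raise InvalidParameterError("sigma_ni and sigma_h must be > 0")

    @property
    def delta_hat(self) -> float:
        """Observed retention fraction 1 - mu_ni_hat/mu_h_hat."""
        if self.mu_h_hat == 0:
            raise DegenerateDenominatorError("historical effect estimate is zero")
        return 1.0 - self.mu_ni_hat / self.mu_h_hat


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test: p-value, decision and enough metadata to rerun it."""

    method: str
    statistic: Optional[float]
    p_value: float
    delta0: float
    alpha: float
    reject: bool
    mc_draws: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidParameterError(f"p_value {self.p_value} outside [0, 1]")
        if self.reject != (self.p_value < self.alpha):
            raise InvalidParameterError("reject flag inconsistent with p < alpha")


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise InvalidParameterError(f"alpha must be in (0, 1), got {alpha}")


def rothmann_test(summary: TrialSummary, delta0: float, alpha: float = 0.025) -> TestResult:
    """Rothmann's synthesis test; p-value is the lower standard-normal tail."""
    _check_alpha(alpha)
    se = math.hypot(summary.sigma_ni, (1.0 - delta0) * summary.sigma_h)
    z = (summary.mu_ni_hat - (1.0 - delta0) * summary.mu_h_hat) / se
    p = float(ndtr(z))
    return TestResult("rothmann", z, p, delta0, alpha, p < alpha)


def wang_test(summary: TrialSummary, delta0: float, alpha: float = 0.025) -> TestResult:
    """Wang's test on the standardized retention fraction; upper normal tail.

    Undefined when the historical effect estimate is exactly zero.
    """
    _check_alpha(alpha)
    h = summary.mu_h_hat
    if h == 0:
        raise DegenerateDenominatorError("historical effect estimate is zero")
    var = summary.sigma_ni**2 + (1.0 - delta0) ** 2 * summary.sigma_h**2
    w = (summary.delta_hat - delta0) / math.sqrt(var / h**2)
    p = float(ndtr(-w))
    return TestResult("wang", w, p, delta0, alpha, p < alpha)


def estimate_b_r(summary: TrialSummary) -> tuple[float, float]:
    """Plug-in estimates (b_hat, r_hat) = (mu_h_hat/sigma_h, sigma_ni/sigma_h)."""
    return summary.mu_h_hat / summary.sigma_h, summary.sigma_ni / summary.sigma_h


def ratio_test(summary: TrialSummary, delta0: float, alpha: float = 0.025) -> TestResult:
    """Exact ratio test: upper tail of the Cauchy-like null law at z_hat.

    The p-value is computed from the integrated CDF directly,
    p = 1 - G_{b_hat, r_hat, delta0}(z_hat), avoiding quantile inversion.
    """
    _check_alpha(alpha)
    if summary.mu_h_hat == 0:
        raise DegenerateDenominatorError("historical effect estimate is zero")
    z_hat = summary.delta_hat
    b_hat, r_hat = estimate_b_r(summary)
    params = NullBoundaryParams(b=b_hat, r=r_hat, delta0=delta0)
    p = 1.0 - cauchy_like_cdf(z_hat, params)
    p = min(1.0, max(0.0, p))
    return TestResult("ratio", z_hat, p, delta0, alpha, p < alpha)
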