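"""Type-I-error and power simulation for the four retention NI tests.

A simulation cell is described by the standardized design parameters:
delta0 (null retention level), the true retention delta, the historical
control effect mu_H (default 0.24), the standardized control effect
b = mu_H/sigma_H and the ratio b/r = mu_H/sigma_NI.  From these,

    sigma_H  = mu_H / b,       sigma_NI = mu_H / (b/r),
    mu_NI    = mu_H * (1 - delta_true).

Two engines share this description:

* ``simulate_summary_tests`` — the estimator-level model of the summary
  tests: each replicate draws single estimates m_hat ~ N(mu_NI, sigma_NI^2)
  and h_hat ~ N(mu_H, sigma_H^2) and applies Rothmann's, Wang's and/or the
  ratio test with known sigmas (the ratio test re-estimates b from h_hat
  each replicate, with r known).
* ``simulate_gpv`` — the raw-data model of the GPV test: each replicate
  draws n_h observations N(mu_H, sigma_H^2) and n_ni observations
  N(mu_NI, sigma_NI^2) — sigma_H and sigma_NI act as per-observation
  standard deviations here — and runs the GPV test with M GPQ draws.

Per-replicate seeds are spawned from the cell seed, and grid constructors
spawn per-cell seeds from one master seed, so any cell (and any replicate)
can be reproduced independently and in parallel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .exceptions import InvalidParameterError, WrongEngineError
from .gpq import ArmStats, _ratio_draws
from .ratio_normal import NullBoundaryParams, cauchy_like_cdf

__all__ = [
    "METHODS",
    "SimulationSpec",
    "SimulationResult",
    "simulate_summary_tests",
    "simulate_gpv",
    "run_grid",
    "table1_specs",
    "table2_specs",
    "fig1_specs",
]

METHODS = ("rothmann", "wang", "ratio", "gpv")
SUMMARY_METHODS = ("rothmann", "wang", "ratio")


@dataclass(frozen=True)
class SimulationSpec:
    """One simulation cell: design parameters, sizes, seed and methods."""

    delta0: float
    delta_true: float
    b: float
    b_over_r: float
    mu_h: float = 0.24
    n_h: int = 30
    n_ni: int = 30
    n_reps: int = 10000
    gpq_draws: int = 10000
    alpha: float = 0.025
    seed: int = 0
    methods: tuple[str, ...] = METHODS

    def __post_init__(self) -> None:
        if self.mu_h <= 0:
            raise InvalidParameterError("mu_h must be > 0 (it sets the sigma scale)")
        if self.b <= 0 or self.b_over_r <= 0:
            raise InvalidParameterError("b and b_over_r must be > 0")
        if self.n_h < 2 or self.n_ni < 2:
            raise InvalidParameterError("arm sizes must be >= 2")
        if self.n_reps < 1 or self.gpq_draws < 1:
            raise InvalidParameterError("n_reps and gpq_draws must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise InvalidParameterError("alpha must be in (0, 1)")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise InvalidParameterError(f"unknown methods: {sorted(unknown)}")

    @property
    def sigma_h(self) -> float:
        return self.mu_h / self.b

    @property
    def sigma_ni(self) -> float:
        return self.mu_h / self.b_over_r

    @property
    def r(self) -> float:
        return self.b / self.b_over_r

    @property
    def mu_ni(self) -> float:
        return self.mu_h * (1.0 - self.delta_true)


@dataclass(frozen=True)
class SimulationResult:
    """Estimated rejection rates of one cell with binomial standard errors."""

    spec: SimulationSpec
    rejection_rate: dict[str, float]
    mc_se: dict[str, float]
    n_reps: int


def _binom_se(rate: float, n: int) -> float:
    return math.sqrt(rate * (1.0 - rate) / n)


def simulate_summary_tests(spec: SimulationSpec) -> SimulationResult:
    """Estimator-level simulation of Rothmann's, Wang's and the ratio test."""
    if "gpv" in spec.methods:
        raise WrongEngineError(
            "the GPV test simulates raw per-arm data; use simulate_gpv"
        )
    methods = tuple(m for m in SUMMARY_METHODS if m in spec.methods)
    if not methods:
        raise InvalidParameterError("no summary-test methods requested")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    m_hat = rng.normal(spec.mu_ni, spec.sigma_ni, spec.n_reps)
    h_hat = rng.normal(spec.mu_h, spec.sigma_h, spec.n_reps)
    d0, alpha = spec.delta0, spec.alpha

    rates: dict[str, float] = {}
    se = math.hypot(spec.sigma_ni, (1.0 - d0) * spec.sigma_h)
    z_r = (m_hat - (1.0 - d0) * h_hat) / se
    if "rothmann" in methods:
        rates["rothmann"] = float(np.mean(ndtr(z_r) < alpha))
    if "wang" in methods:
        # W = -Z_R * sign(h_hat); h_hat == 0 has probability zero
        w = -z_r * np.sign(h_hat)
        rates["wang"] = float(np.mean(ndtr(-w) < alpha))
    if "ratio" in methods:
        # plug-in b_hat per replicate, r known (sigmas known in simulation)
        z_hat = 1.0 - m_hat / h_hat
        b_hat = h_hat / spec.sigma_h
        rej = 0
        for z_i, b_i in zip(z_hat, b_hat):
            params = NullBoundaryParams(b=float(b_i), r=spec.r, delta0=d0)
            rej += (1.0 - cauchy_like_cdf(float(z_i), params)) < alpha
        rates["ratio"] = rej / spec.n_reps

    ses = {m: _binom_se(v, spec.n_reps) for m, v in rates.items()}
    return SimulationResult(spec=spec, rejection_rate=rates, mc_se=ses, n_reps=spec.n_reps)


def simulate_gpv(spec: SimulationSpec) -> SimulationResult:
    """Raw-data simulation of the GPV test.

    Each replicate spawns a data substream and a GPQ substream from the cell
    seed, draws the two normal arms, and computes the GPV with M = gpq_draws.
    """
    thr = 1.0 - spec.delta0
    s_h, s_ni = spec.sigma_h, spec.sigma_ni
    mu_h, mu_ni = spec.mu_h, spec.mu_ni
    n_h, n_ni, M = spec.n_h, spec.n_ni, spec.gpq_draws

    rejections = 0
    for child in np.random.SeedSequence(spec.seed).spawn(spec.n_reps):
        ss_data, ss_gpq = child.spawn(2)
        rng = np.random.default_rng(ss_data)
        x_h = rng.normal(mu_h, s_h, n_h)
        y_ni = rng.normal(mu_ni, s_ni, n_ni)
        stats_h = ArmStats(float(x_h.mean()), float(x_h.var(ddof=1)), n_h)
        stats_ni = ArmStats(float(y_ni.mean()), float(y_ni.var(ddof=1)), n_ni)
        draws = _ratio_draws(stats_h, stats_ni, M, ss_gpq)
        p = np.mean(draws >= thr)
        rejections += p < spec.alpha

    rate = rejections / spec.n_reps
    return SimulationResult(
        spec=spec,
        rejection_rate={"gpv": rate},
        mc_se={"gpv": _binom_se(rate, spec.n_reps)},
        n_reps=spec.n_reps,
    )


def run_cell(spec: SimulationSpec) -> SimulationResult:
    """Run one cell, routing methods to the appropriate engine."""
    rates: dict[str, float] = {}
    ses: dict[str, float] = {}
    summary = tuple(m for m in spec.methods if m in SUMMARY_METHODS)
    if summary:
        res = simulate_summary_tests(replace(spec, methods=summary))
        rates.update(res.rejection_rate)
        ses.update(res.mc_se)
    if "gpv" in spec.methods:
        res = simulate_gpv(replace(spec, methods=("gpv",)))
        rates.update(res.rejection_rate)
        ses.update(res.mc_se)
    return SimulationResult(spec=spec, rejection_rate=rates, mc_se=ses, n_reps=spec.n_reps)


def run_grid(grid: Iterable[SimulationSpec]) -> pd.DataFrame:
    """Run a grid of cells and return a tidy table.

    One row per (cell, method), keyed by (delta0, delta_true, b, b_over_r,
    n_h, n_ni, method); deterministic ordering follows the input order.
    """
    specs = list(grid)
    if not specs:
        raise InvalidParameterError("empty simulation grid")
    rows = []
    for spec in specs:
        result = run_cell(spec)
        for method in spec.methods:
            rows.append(
                {
                    "delta0": spec.delta0,
                    "delta_true": spec.delta_true,
                    "b": spec.b,
                    "b_over_r": spec.b_over_r,
                    "n_h": spec.n_h,
                    "n_ni": spec.n_ni,
                    "method": method,
                    "rejection_rate": result.rejection_rate[method],
                    "mc_se": result.mc_se[method],
                    "n_reps": spec.n_reps,
                    "gpq_draws": spec.gpq_draws if method == "gpv" else None,
                    "alpha": spec.alpha,
                    "seed": spec.seed,
                }
            )
    return pd.DataFrame(rows)


def _cell_seeds(master_seed: int, k: int) -> list[int]:
    """Counter-based per-cell seeds derived from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(k)
    return [int(c.generate_state(1, dtype=np.uint32)[0]) for c in children]


def table1_specs(
    master_seed: int = 0,
    n_reps: int = 10000,
    gpq_draws: int = 10000,
    methods: Sequence[str] = METHODS,
    delta0_grid: Sequence[float] = (0.5, 0.7, 0.9, 1.1, 1.2),
    b_grid: Sequence[float] = (2, 3, 4),
    b_over_r_grid: Sequence[float] = (2, 4, 8),
    n: int = 30,
) -> list[SimulationSpec]:
    """Null-boundary (type-I error) grid: 45 cells, delta_true = delta0."""
    cells = [(d0, b, br) for d0 in delta0_grid for b in b_grid for br in b_over_r_grid]
    seeds = _cell_seeds(master_seed, len(cells))
    return [
        SimulationSpec(
            delta0=d0, delta_true=d0, b=b, b_over_r=br, n_h=n, n_ni=n,
            n_reps=n_reps, gpq_draws=gpq_draws, seed=s, methods=tuple(methods),
        )
        for (d0, b, br), s in zip(cells, seeds)
    ]


def table2_specs(
    master_seed: int = 0,
    n_reps: int = 10000,
    gpq_draws: int = 10000,
    n_grid: Sequence[int] = (30, 40, 50),
    b: float = 2.0,
    b_over_r_grid: Sequence[float] = (2, 4, 8),
    delta0: float = 0.5,
    delta1: float = 0.625,
) -> list[SimulationSpec]:
    """GPV size-and-power grid over equal sample sizes: 18 cells."""
    cells = [
        (n, br, dt)
        for n in n_grid
        for br in b_over_r_grid
        for dt in (delta0, delta1)
    ]
    seeds = _cell_seeds(master_seed, len(cells))
    return [
        SimulationSpec(
            delta0=delta0, delta_true=dt, b=b, b_over_r=br, n_h=n, n_ni=n,
            n_reps=n_reps, gpq_draws=gpq_draws, seed=s, methods=("gpv",),
        )
        for (n, br, dt), s in zip(cells, seeds)
    ]


def fig1_specs(
    master_seed: int = 0,
    n_reps: int = 10000,
    gpq_draws: int = 10000,
    delta_grid: Sequence[float] = (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8),
    b_grid: Sequence[float] = (2, 3, 4),
    b_over_r_grid: Sequence[float] = (2, 4, 8),
    delta0: float = 0.5,
    n: int = 30,
) -> list[SimulationSpec]:
    """Power-curve grid: all four methods across true retention levels."""
    cells = [(dt, b, br) for dt in delta_grid for b in b_grid for br in b_over_r_grid]
    seeds = _cell_seeds(master_seed, len(cells))
    return [
        SimulationSpec(
            delta0=delta0, delta_true=dt, b=b, b_over_r=br, n_h=n, n_ni=n,
            n_reps=n_reps, gpq_draws=gpq_draws, seed=s, methods=METHODS,
        )
        for (dt, b, br), s in zip(cells, seeds)
    ]
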