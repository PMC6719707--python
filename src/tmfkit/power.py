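"""Detectability of trophic magnification in study designs.

A TMF study ultimately tests whether the slope of log concentration on
trophic level differs from 0 (TMF ≠ 1).  Whether that test can succeed
depends on the number of samples, the TL spread of the design, and the
residual scatter of the log concentrations.  This module provides a
Monte-Carlo power estimate for a scenario and the analytic minimal
detectable slope from the noncentral-t power function of the slope
test, reported with its equivalent TMF (10^slope).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import scipy.optimize
import scipy.stats
from pydantic import BaseModel, Field, field_validator

TLDistribution = Union[tuple[float, float], Sequence[float]]


class PowerScenario(BaseModel):
    """One simulated study design.

    ``tl_distribution`` is either an interval (TLs drawn uniformly per
    replicate) or an explicit list of ``n`` TLs (a fixed design).
    ``true_slope`` and ``resid_sd`` are in log10 units per TL and log10
    units, respectively.
    """

    n: int = Field(ge=4)
    tl_distribution: tuple[float, float] | list[float] = (2.0, 4.0)
    true_slope: float = 0.0
    resid_sd: float = Field(gt=0)
    alpha: float = 0.05
    n_reps: int = Field(default=1000, ge=100)
    seed: int = 0

    @field_validator("alpha")
    @classmethod
    def _alpha_open(cls, v):
        if not (0.0 < v < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        return v

    @field_validator("tl_distribution")
    @classmethod
    def _check_tls(cls, v):
        if isinstance(v, tuple):
            if not v[0] < v[1]:
                raise ValueError("uniform TL interval must be increasing")
        elif len(set(v)) < 2:
            raise ValueError("explicit TL list needs >=2 distinct values")
        return v


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    mc_se: float
    n_reps: int


def _design_tls(scenario: PowerScenario, rng: np.random.Generator) -> np.ndarray:
    tl = scenario.tl_distribution
    if isinstance(tl, tuple):
        return rng.uniform(tl[0], tl[1], size=(scenario.n_reps, scenario.n))
    arr = np.asarray(tl, dtype=float)
    if arr.size != scenario.n:
        raise ValueError(
            f"explicit TL list has {arr.size} values but n={scenario.n}"
        )
    return np.broadcast_to(arr, (scenario.n_reps, scenario.n))


def simulate_power(scenario: PowerScenario) -> PowerEstimate:
    """Monte-Carlo power of the two-sided OLS slope test.

    Each replicate draws TLs per the design, simulates
    y = true_slope·TL + N(0, resid_sd²), fits the slope by OLS, and the
    power is the fraction of replicates with slope p-value < alpha.
    Fully vectorized and reproducible from the scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    x = _design_tls(scenario, rng)
    y = scenario.true_slope * x + rng.normal(
        0.0, scenario.resid_sd, size=(scenario.n_reps, scenario.n)
    )
    n = scenario.n
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = np.sum((x - xm) ** 2, axis=1)
    slope = np.sum((x - xm) * (y - ym), axis=1) / sxx
    resid = (y - ym) - slope[:, None] * (x - xm)
    df = n - 2
    s2 = np.sum(resid**2, axis=1) / df
    se = np.sqrt(s2 / sxx)
    tstat = slope / se
    pvals = 2.0 * scipy.stats.t.sf(np.abs(tstat), df)
    power = float(np.mean(pvals < scenario.alpha))
    mc_se = float(np.sqrt(power * (1.0 - power) / scenario.n_reps))
    return PowerEstimate(power=power, mc_se=mc_se, n_reps=scenario.n_reps)


def _design_sxx(n: int, tl_distribution: TLDistribution) -> float:
    if isinstance(tl_distribution, tuple):
        lo, hi = tl_distribution
        # expected centered sum of squares of n iid uniforms
        return (n - 1) * (hi - lo) ** 2 / 12.0
    arr = np.asarray(tl_distribution, dtype=float)
    if arr.size != n:
        raise ValueError(f"explicit TL list has {arr.size} values but n={n}")
    return float(np.sum((arr - arr.mean()) ** 2))


def analytic_power(
    slope: float,
    n: int,
    tl_distribution: TLDistribution,
    resid_sd: float,
    alpha: float = 0.05,
) -> float:
    """Exact power of the two-sided slope t-test for a fixed design.

    The t statistic follows a noncentral t with n−2 df and
    noncentrality b·sqrt(Sxx)/σ.  For a uniform-interval design the
    expected Sxx, (n−1)·range²/12, is used (an approximation; exact for
    explicit TL lists).
    """
    if resid_sd <= 0:
        raise ValueError("resid_sd must be positive")
    df = n - 2
    sxx = _design_sxx(n, tl_distribution)
    ncp = slope * np.sqrt(sxx) / resid_sd
    tcrit = scipy.stats.t.ppf(1.0 - alpha / 2.0, df)
    nct = scipy.stats.nct(df, ncp)
    power = float(1.0 - nct.cdf(tcrit) + nct.cdf(-tcrit))
    if not np.isfinite(power):
        # scipy's noncentral t underflows at very large |ncp|; the normal
        # approximation is exact to working precision there
        power = float(
            scipy.stats.norm.sf(tcrit - ncp) + scipy.stats.norm.cdf(-tcrit - ncp)
        )
    return power


@dataclass(frozen=True)
class DetectableSlope:
    slope: float  # log10 per TL
    tmf: float  # 10^slope
    target_power: float
    alpha: float


def minimal_detectable_slope(
    n: int,
    tl_distribution: TLDistribution = (2.0, 4.0),
    resid_sd: float = 0.5,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> DetectableSlope:
    """Smallest positive slope detectable with the target power.

    Solved by root finding on the analytic noncentral-t power
    function.  In the limit resid_sd → 0 the detectable slope tends to
    0 (any magnification is detectable).
    """
    if not (alpha < target_power < 1.0):
        raise ValueError("target_power must lie in (alpha, 1)")

    def gap(b: float) -> float:
        return analytic_power(b, n, tl_distribution, resid_sd, alpha) - target_power

    hi = max(resid_sd, 1e-6)
    for _ in range(200):
        if gap(hi) > 0:
            break
        hi *= 2.0
    else:
        raise RuntimeError("target power unreachable for this design")
    slope = float(scipy.optimize.brentq(gap, 0.0, hi, xtol=1e-12, rtol=1e-12))
    return DetectableSlope(
        slope=slope, tmf=10.0 ** slope, target_power=target_power, alpha=alpha
    )
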