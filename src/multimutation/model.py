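"""Closed-form prevalence and incidence curves of the multimutation model.

For a susceptible individual the probability of onset by age ``t`` is the
product of the per-mutation exponential CDFs,

    P_s(t, r) = [1 - exp(-r k1 t)]^m1 [1 - exp(-r k2 t)],

the distribution of the maximum of ``m1`` Exp(r k1) waiting times and one
Exp(r k2) waiting time.  The population prevalence multiplies this by the
lifetime susceptible fraction ``f_s``.  All ages are continuous years.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .params import ModelParams

__all__ = [
    "susceptible_prevalence",
    "population_prevalence",
    "susceptible_incidence_rate",
    "incidence_rate",
    "peak_onset_age",
    "mean_onset_age",
    "mutation_mean_times",
    "SolverError",
    "DegenerateCohortError",
]

#: Absolute tolerance for one-dimensional quadrature (integrands are smooth).
QUAD_ABS_TOL = 1e-8
#: Absolute tolerance, in years, for age-valued root/optimum searches.
AGE_TOL = 1e-6


class SolverError(RuntimeError):
    """A bracketing/root/optimum search failed to locate a solution."""


class DegenerateCohortError(ValueError):
    """The cohort window carries no probability mass (zero denominator)."""


def _check_ages(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("ages must be nonnegative")
    return t


def susceptible_prevalence(params: ModelParams, t):
    """P_s(t, r): onset probability by age ``t`` given susceptibility.

    Accepts a scalar age or an array of ages (vectorized).  Satisfies the
    rescaling identity ``P_s(t, r) == P_s(r t, 1)`` exactly.
    """
    t = _check_ages(t)
    tau = params.r * t
    out = (-np.expm1(-params.k1 * tau)) ** params.m1 * (-np.expm1(-params.k2 * tau))
    return out if out.ndim else float(out)


def population_prevalence(params: ModelParams, t):
    """P(t) = f_s * P_s(t, r): unconditional cumulative risk by age ``t``."""
    return params.f_s * susceptible_prevalence(params, t)


def susceptible_incidence_rate(params: ModelParams, t):
    """IR_s(t) = dP_s/dt, per year, from the analytic derivative."""
    t = _check_ages(t)
    r, k1, k2, m1 = params.r, params.k1, params.k2, params.m1
    e1 = np.exp(-r * k1 * t)
    e2 = np.exp(-r * k2 * t)
    p1 = -np.expm1(-r * k1 * t)
    p2 = -np.expm1(-r * k2 * t)
    if m1 == 0:
        out = r * k2 * e2
    else:
        out = m1 * r * k1 * e1 * p1 ** (m1 - 1) * p2 + p1**m1 * r * k2 * e2
    return out if np.ndim(out) else float(out)


def incidence_rate(params: ModelParams, t):
    """Population fractional incidence rate IR(t) = f_s * dP_s/dt, per year."""
    return params.f_s * susceptible_incidence_rate(params, t)


def peak_onset_age(params: ModelParams, t_max: float = 300.0) -> float:
    """Age at which the susceptible incidence-rate curve peaks.

    Located by golden-section/Brent minimisation of ``-IR_s`` on
    ``(0, t_max)`` to an absolute tolerance of 1e-6 years.  Requires
    ``m >= 2``: with a single exponential stage the incidence rate is
    monotone decreasing and has no interior maximum.
    """
    if params.m < 2:
        raise SolverError("incidence rate is monotone for m = 1; no interior peak")
    res = minimize_scalar(
        lambda t: -susceptible_incidence_rate(params, t),
        bounds=(AGE_TOL, t_max),
        method="bounded",
        options={"xatol": AGE_TOL / 10},
    )
    if not res.success or res.x >= t_max * (1 - 1e-9) or res.x <= AGE_TOL * 2:
        raise SolverError("failed to bracket an interior incidence maximum")
    return float(res.x)


def mean_onset_age(params: ModelParams, t_L: float, t_H: float) -> float:
    """Mean onset age of cases arising in the age window ``[t_L, t_H]``.

        t_bar = int_{t_L}^{t_H} t dP_s(t, r) / [P_s(t_H, r) - P_s(t_L, r)]

    evaluated by adaptive quadrature of ``t * IR_s(t)``.  The result lies
    strictly inside the window.
    """
    if not 0 <= t_L < t_H:
        raise ValueError(f"need 0 <= t_L < t_H, got [{t_L}, {t_H}]")
    denom = susceptible_prevalence(params, t_H) - susceptible_prevalence(params, t_L)
    if denom <= 0:
        raise DegenerateCohortError(
            f"no onset probability mass in [{t_L}, {t_H}] (denominator {denom})"
        )
    num, _ = quad(
        lambda t: t * susceptible_incidence_rate(params, t),
        t_L,
        t_H,
        epsabs=QUAD_ABS_TOL,
        epsrel=1e-10,
        limit=200,
    )
    return num / denom


def mutation_mean_times(params: ModelParams) -> tuple[float, float]:
    """Mean waiting times (T1, T2) = (1/(r k1), 1/(r k2)) in years."""
    return 1.0 / (params.r * params.k1), 1.0 / (params.r * params.k2)
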