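"""Optimal insulin protocol: glucose clamp, beta recovery, time to remission.

With sugar intake at zero and exogenous insulin continuously adjusted to
hold glucose at a chosen safe target Gmin, the beta-cell pool equations
become linear and solve in closed form:

    beta(t)/betaTOT = exp(-lambda t) * (beta0_frac - beta_inf) + beta_inf,
    lambda   = kRE + kIN*g(Gmin),
    beta_inf = kRE / lambda.

The clamp insulin I* is the positive root of the quadratic obtained from
the steady glucose balance at G = Gmin, and the exogenous flux needed to
maintain it decays exponentially as the recovering beta-cells take over:

    FI(t) = gamma*I* - c*betaTOT*beta_frac(t)*f(Gmin).

Remission is reached when beta regains the healthy fixed-point fraction;
since beta_inf at any Gmin below the healthy fixed-point glucose overshoots
that fraction, this happens in finite time — and never when Gmin is at or
above it.  Lower targets recover faster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import PatientParams
from . import equilibria

__all__ = [
    "RemissionPlan",
    "beta_recovery",
    "recovery_rate",
    "clamp_insulin",
    "insulin_flux_schedule",
    "time_to_remission",
    "plan_remission",
]


class InfeasibleClampError(ValueError):
    """No positive insulin level can hold glucose at the requested target."""


def recovery_rate(Gmin: float, params: PatientParams) -> float:
    """Exponential rate lambda = kRE + kIN*g(Gmin) of the clamped pools (1/day)."""
    return params.kRE + params.kIN * params.g(Gmin)


def beta_recovery(t, Gmin: float, beta0_frac: float,
                  params: PatientParams):
    """Active beta-cell fraction at time t under a glucose clamp at Gmin.

    Exact solution of the death-free pool equations with G held at Gmin;
    monotone from ``beta0_frac`` toward ``kRE/(kRE + kIN*g(Gmin))``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not 0.0 <= beta0_frac <= 1.0:
        raise ValueError("beta0_frac must lie in [0, 1]")
    lam = recovery_rate(Gmin, params)
    beta_inf = params.kRE / lam
    out = np.exp(-lam * t) * (beta0_frac - beta_inf) + beta_inf
    return out if out.ndim else float(out)


def clamp_insulin(Gmin: float, params: PatientParams) -> float:
    """Plasma insulin I* holding glucose steady at Gmin with no meals.

    Positive root of  SI*Gmin*I^2 + Gmin*(SE + SI*I0)*I + SE*Gmin*I0 - m0 = 0.
    """
    if Gmin <= 0:
        raise InfeasibleClampError("clamp target must be positive")
    p = params
    a = p.SI * Gmin
    b = Gmin * (p.SE + p.SI * p.I0)
    c = p.SE * Gmin * p.I0 - p.m0
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise InfeasibleClampError("no real insulin root for this target")
    root = (-b + np.sqrt(disc)) / (2.0 * a)
    if root <= 0:
        raise InfeasibleClampError("no positive insulin root for this target")
    return float(root)


def healthy_beta_fraction(params: PatientParams) -> float:
    """Active fraction at the meal-free healthy stable fixed point."""
    stable = [fp for fp in equilibria.find_fixed_points(params) if fp.stable]
    if not stable:
        raise ValueError("no stable fixed point")
    fp = min(stable, key=lambda q: q.G)
    return fp.beta / params.betaTOT


def presenting_beta_fraction(params: PatientParams) -> float:
    """Active fraction at the hyperglycemic (low-beta) stable fixed point.

    The default presenting state of an untreated patient after onset.
    """
    stable = [fp for fp in equilibria.find_fixed_points(params) if fp.stable]
    if len(stable) < 2:
        raise ValueError("not in a bistable regime")
    fp = max(stable, key=lambda q: q.G)
    return fp.beta / params.betaTOT


def insulin_flux_schedule(Gmin: float, beta0_frac: float,
                          params: PatientParams, horizon: float = 120.0,
                          n: int = 481):
    """Exogenous insulin flux FI(t) maintaining the clamp, sampled on [0, horizon].

    FI(t) = gamma*I* - c*betaTOT*beta_frac(t)*f(Gmin), clipped at zero
    (clipping flagged: past that point the clamp would need glucose, not
    insulin, to stay at Gmin).

    Returns (t, FI, clipped).
    """
    I_star = clamp_insulin(Gmin, params)
    t = np.linspace(0.0, horizon, n)
    frac = beta_recovery(t, Gmin, beta0_frac, params)
    FI = params.gamma * I_star - params.cmax * params.betaTOT * frac \
        * params.f(Gmin)
    clipped = bool(np.any(FI < 0))
    return t, np.clip(FI, 0.0, None), clipped


def time_to_remission(Gmin: float, beta0_frac: float | None,
                      params: PatientParams,
                      epsilon: float = 0.0) -> float:
    """Clamp duration (days) for beta to regain its healthy fixed-point value.

    Inverts the closed-form recovery: with lambda = kRE + kIN*g(Gmin) and
    beta_inf = kRE/lambda,

        t = (1/lambda) * ln((beta_inf - beta0) / (beta_inf - beta_target)),

    where beta_target is the healthy stable fixed-point fraction (minus
    ``epsilon`` if a within-epsilon criterion is preferred).  Returns
    ``inf`` when beta_inf does not exceed the target — i.e. whenever the
    clamp target is at or above the healthy fixed-point glucose.

    ``beta0_frac=None`` uses the presenting patient state: the low-beta
    stable fixed point's fraction (requires a bistable regime).
    """
    stable = [fp for fp in equilibria.find_fixed_points(params) if fp.stable]
    if len(stable) < 2:
        raise ValueError("time_to_remission applies only in a bistable regime")
    target = min(stable, key=lambda q: q.G).beta / params.betaTOT - epsilon
    if beta0_frac is None:
        beta0_frac = max(stable, key=lambda q: q.G).beta / params.betaTOT
    if beta0_frac >= target:
        return 0.0
    lam = recovery_rate(Gmin, params)
    beta_inf = params.kRE / lam
    if beta_inf <= target:
        return float("inf")
    return float(np.log((beta_inf - beta0_frac) / (beta_inf - target)) / lam)


@dataclass
class RemissionPlan:
    """A complete clamp-treatment plan for one patient."""

    Gmin: float                 # clamp target, mg/dL
    I_star: float               # clamp plasma insulin, uU/mL
    lam: float                  # recovery rate kRE + kIN*g(Gmin), 1/day
    beta_inf_frac: float        # asymptotic active fraction kRE/lam
    beta0_frac: float           # starting active fraction
    t_remission: float          # days, or inf
    t: np.ndarray               # schedule sample times, days
    FI: np.ndarray              # exogenous insulin flux, uU/mL/day
    FI_clipped: bool            # True if the schedule hit zero

    def to_dict(self) -> dict:
        return {
            "Gmin_mg_per_dL": self.Gmin,
            "I_star_uU_per_mL": self.I_star,
            "lambda_per_day": self.lam,
            "beta_inf_frac": self.beta_inf_frac,
            "beta0_frac": self.beta0_frac,
            "t_remission_days": (self.t_remission
                                 if np.isfinite(self.t_remission) else "inf"),
            "FI_clipped": self.FI_clipped,
        }


def plan_remission(Gmin: float, params: PatientParams,
                   beta0_frac: float | None = None,
                   horizon: float | None = None) -> RemissionPlan:
    """Assemble the full remission plan for a clamp target Gmin."""
    if beta0_frac is None:
        beta0_frac = presenting_beta_fraction(params)
    t_rem = time_to_remission(Gmin, beta0_frac, params)
    if horizon is None:
        horizon = 1.5 * t_rem if np.isfinite(t_rem) else 120.0
    t, FI, clipped = insulin_flux_schedule(Gmin, beta0_frac, params,
                                           horizon=horizon)
    return RemissionPlan(
        Gmin=Gmin, I_star=clamp_insulin(Gmin, params),
        lam=recovery_rate(Gmin, params),
        beta_inf_frac=params.kRE / recovery_rate(Gmin, params),
        beta0_frac=float(beta0_frac), t_remission=t_rem, t=t, FI=FI,
        FI_clipped=clipped)
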