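"""Core state, parameters and right-hand side of the KPD glucose-insulin model.

The model couples three timescales:

* fast (minutes-hours): plasma glucose ``G`` and insulin ``I`` in the
  classic negative feedback loop — glucose stimulates insulin secretion,
  insulin promotes glucose disposal and suppresses hepatic glucose
  production (HGP);
* intermediate (days-weeks): reversible glucotoxic inactivation of
  beta-cells, moving mass between an active pool ``beta`` and an inactive
  pool ``beta_IN`` at glucose-dependent rate ``kIN*g(G)`` and
  glucose-independent recovery rate ``kRE``;
* slow (months-years): irreversible beta-cell death at rate ``kD*h(G)``,
  and adaptation of the per-cell secretory capacity ``c`` toward a target
  fasting glucose ``G0``, saturating at ``cmax``.

All response functions are Hill functions of order 2 in glucose.

Units: glucose mg/dL, insulin uU/mL, time days.  Beta-cell mass is
dimensionless (``betaTOT`` normalised to 1) with ``cmax`` carrying the
secretion scale: only the product ``beta*c*f(G)`` enters the dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import numpy as np

__all__ = [
    "PatientParams",
    "PhysioState",
    "ExogenousInputs",
    "hill",
    "rhs",
    "adaptation_rate",
    "STATE_NAMES",
    "PARAM_NAMES",
]

STATE_NAMES = ("G", "I", "beta", "betaIN", "c")

PARAM_NAMES = (
    "SE", "SI", "gamma", "m0", "I0", "Kf", "Kg", "Kh",
    "kIN", "kRE", "kD", "betaTOT", "cmax", "G0", "ka",
)


def hill(G, K):
    """Second-order Hill response ``G**2 / (G**2 + K**2)``.

    Strictly increasing in ``G`` on [0, inf), 0.5 at ``G == K``, tending to
    1 as ``G -> inf``.  Accepts scalars or arrays in ``G``.

    Parameters
    ----------
    G : float or array_like
        Glucose concentration, mg/dL.  Must be >= 0.
    K : float
        Hill midpoint, mg/dL.  Must be > 0.
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("hill: glucose must be non-negative")
    if K <= 0:
        raise ValueError("hill: midpoint K must be positive")
    G2 = G * G
    out = G2 / (G2 + K * K)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class PatientParams:
    """All rate constants and sensitivities for one simulated patient.

    Defaults for the fast glucose-insulin subsystem follow the published
    minimal model of long-term glucose regulation (gamma, SE, SI, Kf and
    the HGP scale R0 from which m0 derives); see :mod:`kpdsim.calibration`
    for how the remaining defaults are derived.

    Attributes
    ----------
    SE : float
        Insulin-independent glucose clearance rate (1/day).
    SI : float
        Insulin sensitivity (mL/uU/day).
    gamma : float
        Insulin clearance rate (1/day).
    m0 : float
        Hepatic-production scale (mg*uU/dL/mL/day); HGP is ``m0/(I0+I)``.
    I0 : float
        Insulin at which HGP is half its zero-insulin value (uU/mL).
    Kf, Kg, Kh : float
        Hill midpoints (mg/dL) of insulin secretion f, reversible
        inactivation g, and irreversible death h.  Bistability requires
        Kg >> Kf.
    kIN, kRE, kD : float
        Reversible inactivation, reactivation, and death rates (1/day).
    betaTOT : float
        Total beta-cell mass (dimensionless; 1 by default).
    cmax : float
        Maximum per-cell secretory capacity (uU/mL/day per unit beta).
    G0 : float
        Adaptation target fasting glucose (mg/dL), 80 by default.
    ka : float
        Adaptation rate, as fraction of cmax per (mg/dL * day).
    """

    SE: float = 1.44
    SI: float = 0.72
    gamma: float = 432.0
    m0: float = 8640.0
    I0: float = 5.0
    Kf: float = float(np.sqrt(20000.0))
    Kg: float = 4081.2579760003737
    Kh: float = 250.0
    kIN: float = 4.8
    kRE: float = 0.04
    kD: float = 1e-3
    betaTOT: float = 1.0
    cmax: float = 8785.72770488011
    G0: float = 80.0
    ka: float = 1e-3

    def __post_init__(self):
        for name in PARAM_NAMES:
            if name in ("kD", "ka"):
                if getattr(self, name) < 0:
                    raise ValueError(f"PatientParams.{name} must be >= 0")
            elif getattr(self, name) <= 0:
                raise ValueError(f"PatientParams.{name} must be > 0")
        if self.Kg <= self.Kf:
            raise ValueError("PatientParams requires Kg > Kf")

    # Hill responses bound to this patient's midpoints
    def f(self, G):
        """Insulin-secretion response f(G)."""
        return hill(G, self.Kf)

    def g(self, G):
        """Reversible-inactivation response g(G)."""
        return hill(G, self.Kg)

    def h(self, G):
        """Irreversible-death response h(G)."""
        return hill(G, self.Kh)

    def replace(self, **changes) -> "PatientParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "PatientParams":
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in mapping.items()})


@dataclass
class PhysioState:
    """Instantaneous physiological state (G, I, beta, beta_IN, c)."""

    G: float
    I: float
    beta: float
    betaIN: float
    c: float

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.I, self.beta, self.betaIN, self.c])

    @classmethod
    def from_array(cls, y) -> "PhysioState":
        return cls(*(float(v) for v in y))

    def validate(self, params: PatientParams | None = None) -> "PhysioState":
        if min(self.G, self.I, self.beta, self.betaIN, self.c) < 0:
            raise ValueError("PhysioState components must be non-negative")
        if params is not None and self.c > params.cmax * (1 + 1e-9):
            raise ValueError("PhysioState.c exceeds cmax")
        return self


@dataclass(frozen=True)
class ExogenousInputs:
    """Exogenous fluxes: meal glucose M (mg/dL/day), insulin FI (uU/mL/day).

    Both must be >= 0 in simulation; equilibrium scans may probe negative
    values for conceptual completeness.
    """

    M: float = 0.0
    FI: float = 0.0


def adaptation_rate(G_fasting: float, c: float, params: PatientParams) -> float:
    """Rate of change of per-cell secretory capacity c (per day).

    Linear in the fasting-glucose error, ``ka*cmax*(Gf - G0)``, hard-clipped
    so that c stays within [0, cmax]: the rate is zero when c is pinned at
    cmax with glucose still high, or at 0 with glucose low.
    """
    rate = params.ka * params.cmax * (G_fasting - params.G0)
    if rate > 0 and c >= params.cmax:
        return 0.0
    if rate < 0 and c <= 0.0:
        return 0.0
    return rate


def rhs(state: PhysioState, params: PatientParams,
        inputs: ExogenousInputs = ExogenousInputs()) -> np.ndarray:
    """Time derivative of (G, I, beta, betaIN, c), per day.

    dG/dt  = M + m0/(I0+I) - (SE + SI*I)*G
    dI/dt  = beta*c*f(G) + FI - gamma*I
    dbeta/dt   = -[kIN*g(G) + kD*h(G)]*beta + kRE*betaIN
    dbetaIN/dt = -[kRE + kD*h(G)]*betaIN + kIN*g(G)*beta
    dc/dt  = adaptation_rate(G, c)

    With kD = 0 the two beta-cell pools are exactly conserved.
    """
    return rhs_array(state.as_array(), params, inputs.M, inputs.FI)


def rhs_array(y: np.ndarray, params: PatientParams,
              M: float = 0.0, FI: float = 0.0) -> np.ndarray:
    """Array-signature right-hand side used by the integrator."""
    G, I, beta, betaIN, c = y
    p = params
    Gp = G if G > 0 else 0.0  # guard Hill forms against tiny negative overshoot
    G2 = Gp * Gp
    f = G2 / (G2 + p.Kf * p.Kf)
    g = G2 / (G2 + p.Kg * p.Kg)
    h = G2 / (G2 + p.Kh * p.Kh)
    dG = M + p.m0 / (p.I0 + I) - (p.SE + p.SI * I) * G
    dI = beta * c * f + FI - p.gamma * I
    inact = p.kIN * g
    death = p.kD * h
    dbeta = -(inact + death) * beta + p.kRE * betaIN
    dbetaIN = -(p.kRE + death) * betaIN + inact * beta
    dc = adaptation_rate(G, c, p)
    return np.array([dG, dI, dbeta, dbetaIN, dc])
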