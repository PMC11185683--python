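"""Derivation of default parameter values and the four phenotype presets.

Only a handful of constants are taken as given: the fast-subsystem rates
(gamma, SE, SI, Kf) and the reference hepatic glucose production R0 come
from the published minimal model of long-term glucose regulation (Topp et
al.); the HGP-suppression midpoint I0 = 5 uU/mL is on the scale of observed
fasting insulin; and the reversible-inactivation Hill midpoint Kg is
anchored by the single printed value g(100 mg/dL) = 6e-4.  Everything else
is derived:

* m0 so that HGP at I = I0 equals R0 (m0 = 2*I0*R0);
* the secretion capacity Q = cmax*betaTOT so that the meal-free fixed
  point of the fast subsystem, with beta at its quasi-steady fraction,
  sits exactly at a prescribed fasting hyperglycemia (110 mg/dL);
* daily meal budgets as fractions of the fasting HGP.

The presets A-D differ only in the glucotoxicity rates (kIN, kRE, kD) and
the recalibrated capacity Q: A is a conventional-T2D-like patient (low
kIN), B a KPD-prone patient (high kIN), C a slow-reactivating KPD patient
(low kRE), D additionally has fast irreversible beta-cell death (high kD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import PatientParams, hill

__all__ = [
    "CalibrationConstants",
    "DEFAULT_CONSTANTS",
    "derive_m0",
    "derive_Kg",
    "fasting_insulin",
    "fasting_hgp",
    "quasi_steady_beta_fraction",
    "calibrate_secretion_capacity",
    "phenotype_presets",
    "PHENOTYPE_RATES",
    "meal_budget",
    "daily_glucose_flux_grams",
]


@dataclass(frozen=True)
class CalibrationConstants:
    """Anchoring constants behind the default calibration.

    R0 : reference hepatic glucose production (mg/dL/day)
    body_mass : kg, for the physiological glucose-flux cross-check
    plasma_volume : L, converts mg/dL/day fluxes to absolute mass
    flux_per_kg : typical whole-body glucose flux (mg/kg/min)
    g_anchor_G, g_anchor_value : the printed anchor g(100 mg/dL) = 6e-4
    """

    R0: float = 864.0
    body_mass: float = 70.0
    plasma_volume: float = 3.5
    flux_per_kg: float = 2.0
    g_anchor_G: float = 100.0
    g_anchor_value: float = 6e-4

    def __post_init__(self):
        if min(self.R0, self.body_mass, self.plasma_volume,
               self.flux_per_kg, self.g_anchor_G, self.g_anchor_value) <= 0:
            raise ValueError("CalibrationConstants must all be positive")


DEFAULT_CONSTANTS = CalibrationConstants()

#: Glucotoxicity rate constants (kIN, kRE, kD) per phenotype, 1/day.
PHENOTYPE_RATES = {
    "A": {"kIN": 4.8, "kRE": 0.04, "kD": 1e-3},
    "B": {"kIN": 71.0, "kRE": 0.04, "kD": 1e-3},
    "C": {"kIN": 71.0, "kRE": 0.028, "kD": 1e-3},
    "D": {"kIN": 71.0, "kRE": 0.028, "kD": 0.07},
}

#: Fasting glucose (mg/dL) all presets are calibrated to.
CALIBRATION_G_TARGET = 110.0


def derive_m0(R0: float, I0: float) -> float:
    """HGP scale m0 such that m0/(I0+I) equals R0 at I = I0, i.e. 2*I0*R0."""
    if R0 < 0 or I0 <= 0:
        raise ValueError("derive_m0 requires R0 >= 0 and I0 > 0")
    return 2.0 * I0 * R0


def derive_Kg(anchor_G: float, anchor_value: float) -> float:
    """Hill midpoint Kg such that hill(anchor_G, Kg) == anchor_value.

    Inverts the order-2 Hill form: Kg = G*sqrt((1-v)/v).
    """
    if anchor_G <= 0:
        raise ValueError("derive_Kg requires anchor_G > 0")
    if not 0.0 < anchor_value < 1.0:
        raise ValueError("derive_Kg requires anchor_value in (0, 1)")
    return anchor_G * float(np.sqrt((1.0 - anchor_value) / anchor_value))


def fasting_insulin(params: PatientParams, G: float) -> float:
    """Steady-state insulin of the glucose equation at meal-free glucose G.

    Solves m0/(I0+I) = G*(SE + SI*I), a quadratic in I; returns the positive
    root.  This is what the plasma insulin must be for G to be stationary at
    zero meal input, regardless of where that insulin comes from.
    """
    if G <= 0:
        raise ValueError("fasting_insulin requires G > 0")
    p = params
    a = p.SI * G
    b = G * (p.SE + p.SI * p.I0)
    c = G * p.SE * p.I0 - p.m0
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("no real insulin root at this glucose")
    root = (-b + np.sqrt(disc)) / (2.0 * a)
    if root <= 0 and c > 0:
        raise ValueError("no positive insulin root at this glucose")
    return float(max(root, 0.0))


def fasting_hgp(params: PatientParams, G: float | None = None) -> float:
    """Hepatic glucose production m0/(I0+I) at the meal-free steady state.

    By default evaluated at the calibration fasting glucose (110 mg/dL).
    """
    if G is None:
        G = CALIBRATION_G_TARGET
    I = fasting_insulin(params, G)
    return params.m0 / (params.I0 + I)


def quasi_steady_beta_fraction(params: PatientParams, G) -> float:
    """Active beta-cell fraction 1/(1 + (kIN/kRE)*g(G)) with pools equilibrated."""
    return 1.0 / (1.0 + (params.kIN / params.kRE) * params.g(G))


def calibrate_secretion_capacity(params: PatientParams,
                                 G_target: float = CALIBRATION_G_TARGET) -> float:
    """Secretion capacity Q = cmax*betaTOT placing a fixed point at G_target.

    With beta at its quasi-steady fraction and c = cmax, the meal-free,
    insulin-free steady state of the fast subsystem requires secretion
    Q*frac(G)*f(G) = gamma*I*(G); solving at G = G_target gives Q.
    """
    if G_target <= 0:
        raise ValueError("calibrate_secretion_capacity requires G_target > 0")
    I_star = fasting_insulin(params, G_target)
    frac = quasi_steady_beta_fraction(params, G_target)
    if frac <= 0:
        raise ValueError("quasi-steady beta fraction must be positive")
    return float(params.gamma * I_star / (frac * params.f(G_target)))


def phenotype_presets(constants: CalibrationConstants = DEFAULT_CONSTANTS,
                      G_target: float = CALIBRATION_G_TARGET,
                      ) -> dict[str, PatientParams]:
    """The four patient phenotypes A-D, fully calibrated.

    All share the fast-subsystem defaults, m0 = 2*I0*R0, and Kg from the
    g(100) = 6e-4 anchor; they differ in (kIN, kRE, kD) and in the secretion
    capacity, which is recalibrated per phenotype so each has a fixed point
    at the same fasting hyperglycemia G_target.
    """
    base = PatientParams(
        m0=derive_m0(constants.R0, PatientParams.I0),
        Kg=derive_Kg(constants.g_anchor_G, constants.g_anchor_value),
    )
    presets = {}
    for name, rates in PHENOTYPE_RATES.items():
        p = base.replace(**rates)
        # betaTOT stays 1; the calibrated product Q is carried by cmax
        presets[name] = p.replace(cmax=calibrate_secretion_capacity(p, G_target))
    return presets


def meal_budget(fraction_of_HGP: float, params: PatientParams) -> float:
    """Total daily meal glucose (mg/dL/day) as a fraction of fasting HGP."""
    if fraction_of_HGP < 0:
        raise ValueError("meal fraction must be >= 0")
    return fraction_of_HGP * fasting_hgp(params)


def daily_glucose_flux_grams(constants: CalibrationConstants = DEFAULT_CONSTANTS) -> float:
    """Whole-body daily glucose flux in grams: flux_per_kg * body_mass * 1440 min."""
    return constants.flux_per_kg * constants.body_mass * 1440.0 / 1000.0
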