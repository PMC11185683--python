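"""Fixed points, stability, bifurcation scans and the regime phase diagram.

Irreversible beta-cell death is slow, so steady states over weeks are
computed with kD neglected.  The beta-cell pools then equilibrate to the
quasi-steady active fraction

    beta(G)/betaTOT = 1 / (1 + (kIN/kRE) * g(G)),

and substituting this (with c fixed) into the glucose balance at constant
meal input M and exogenous insulin flux FI gives a single scalar equation
for the steady-state glucose,

    m0 / (s(G)/gamma + FI/gamma + I0) + M = G * (SE + SI*(s(G)+FI)/gamma),

with s(G) = c*betaTOT*f(G)/(1 + (kIN/kRE)g(G)) the quasi-steady insulin
secretion.  Clearing the Hill denominators turns this into a polynomial in
G of degree <= 9 whose non-negative real roots are the steady-state glucose
values; they are found as eigenvalues of the companion matrix and polished
by Newton steps on the residual.  Stability is judged from the eigenvalues
of the 4-state (G, I, beta, betaIN) Jacobian with c frozen.

The positive feedback of glucotoxicity on glucose makes s(G) non-monotone
for large kIN/kRE, which is what produces the toggle-switch bistability
between a healthy high-beta state and a hyperglycemic low-beta state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly

from .model_core import PatientParams, rhs_array

__all__ = [
    "FixedPoint",
    "RegimeClassification",
    "BifurcationScan",
    "PhaseDiagram",
    "steady_residual",
    "fixed_point_polynomial",
    "find_fixed_points",
    "scan_bifurcation",
    "classify_regime",
    "phase_diagram",
]

#: Physical-root window for glucose, mg/dL.
G_MAX_PHYSICAL = 2000.0


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the death-free model at fixed (M, FI, c)."""

    G: float
    I: float
    beta: float
    betaIN: float
    c: float
    stable: bool
    eigenvalues: tuple
    branch: str  # one of {"high_beta", "low_beta", "intermediate"}

    @property
    def beta_fraction(self) -> float:
        return self.beta / (self.beta + self.betaIN)


@dataclass
class RegimeClassification:
    """Fixed-point structure at M = FI = 0 for one parameter set."""

    regime: str  # monostable_high_beta | bistable | monostable_low_beta
    min_fasting_G: float
    fixed_points: list
    adapted_c: float | None = None  # c < cmax when adaptation floors G at G0

    @property
    def n_stable(self) -> int:
        return sum(fp.stable for fp in self.fixed_points)


def _secretion(params: PatientParams, G, c: float):
    """Quasi-steady insulin secretion s(G) = c*betaTOT*f(G)/(1+(kIN/kRE)g(G))."""
    return c * params.betaTOT * params.f(G) / (
        1.0 + (params.kIN / params.kRE) * params.g(G))


def steady_residual(G, params: PatientParams, M: float = 0.0, FI: float = 0.0,
                    c: float | None = None):
    """Residual of the steady-state glucose balance; zero at a fixed point."""
    if c is None:
        c = params.cmax
    p = params
    Iss = (_secretion(p, G, c) + FI) / p.gamma
    return p.m0 / (Iss + p.I0) + M - G * (p.SE + p.SI * Iss)


def fixed_point_polynomial(params: PatientParams, M: float = 0.0,
                           FI: float = 0.0, c: float | None = None) -> np.ndarray:
    """Ascending coefficients of the steady-state polynomial in G (deg <= 9).

    Obtained by substituting the quasi-steady beta(G) into the glucose
    balance and multiplying through by gamma*(s(G)+FI+gamma*I0) and by the
    Hill denominators of f and of the beta(G) fraction.  The non-negative
    real roots are exactly the steady-state glucose values.
    """
    if c is None:
        c = params.cmax
    p = params
    if p.kRE <= 0:
        raise ValueError("fixed_point_polynomial requires kRE > 0")
    rho = p.kIN / p.kRE
    Kf2, Kg2 = p.Kf ** 2, p.Kg ** 2
    A = np.array([Kf2, 0.0, 1.0])            # G^2 + Kf^2
    B = np.array([Kg2, 0.0, 1.0 + rho])      # (1+rho)G^2 + Kg^2
    D = npoly.polymul(A, B)                  # common denominator of s(G)
    N = c * p.betaTOT * np.array([0.0, 0.0, Kg2, 0.0, 1.0])  # s(G) numerator
    P = npoly.polyadd(N, FI * D)             # gamma*Iss * D
    T = npoly.polyadd(P, p.I0 * p.gamma * D)  # gamma*(Iss+I0) * D
    lhs = npoly.polyadd(p.m0 * p.gamma ** 2 * npoly.polymul(D, D),
                        M * p.gamma * npoly.polymul(D, T))
    clearance = npoly.polyadd(p.gamma * p.SE * D, p.SI * P)
    rhs = npoly.polymul(npoly.polymul([0.0, 1.0], clearance), T)
    coeffs = npoly.polysub(lhs, rhs)
    if not np.any(coeffs):
        raise ValueError("degenerate all-zero fixed-point polynomial")
    # trim numerically-degenerate leading coefficients, judged on the
    # glucose-rescaled polynomial so that unit-driven magnitude differences
    # between degrees do not mask genuine high-order terms
    scaled = coeffs * (100.0 ** np.arange(len(coeffs)))
    keep = np.nonzero(np.abs(scaled) > 1e-12 * np.max(np.abs(scaled)))[0]
    return coeffs[: keep[-1] + 1]


def _jacobian4(y4: np.ndarray, params: PatientParams, M: float, FI: float,
               c: float) -> np.ndarray:
    """Central-difference Jacobian of the (G, I, beta, betaIN) subsystem.

    Evaluated for the death-free (kD = 0) vector field with c frozen, since
    the fixed points being classified are those of the death-free model.
    Because beta + betaIN is conserved when kD = 0, this matrix always has
    an exact zero eigenvalue along the conservation direction; use
    :func:`_stability_eigenvalues` for a sign-definite stability call.
    """
    if params.kD != 0:
        params = params.replace(kD=0.0)
    J = np.empty((4, 4))
    for j in range(4):
        h = 1e-6 * (1.0 + abs(y4[j]))
        yp = np.array([*y4, c]); yp[j] += h
        ym = np.array([*y4, c]); ym[j] -= h
        J[:, j] = (rhs_array(yp, params, M, FI)[:4]
                   - rhs_array(ym, params, M, FI)[:4]) / (2.0 * h)
    return J


def _stability_eigenvalues(y4: np.ndarray, params: PatientParams, M: float,
                           FI: float, c: float) -> np.ndarray:
    """Eigenvalues governing stability, on the beta+betaIN conservation manifold.

    The death-free flow leaves beta + betaIN invariant, so the physically
    relevant Jacobian is the 3-state (G, I, beta) one with betaIN slaved to
    betaIN = S - beta at the point's total S; this removes the structural
    zero mode of the 4-state matrix.
    """
    if params.kD != 0:
        params = params.replace(kD=0.0)
    S = y4[2] + y4[3]

    def f3(x):
        y = np.array([x[0], x[1], x[2], S - x[2], c])
        return rhs_array(y, params, M, FI)[:3]

    x0 = y4[:3]
    J = np.empty((3, 3))
    for j in range(3):
        h = 1e-6 * (1.0 + abs(x0[j]))
        xp = x0.copy(); xp[j] += h
        xm = x0.copy(); xm[j] -= h
        J[:, j] = (f3(xp) - f3(xm)) / (2.0 * h)
    return np.linalg.eigvals(J)


def _secretion_slope_sign(params: PatientParams, G: float) -> float:
    """Sign of d/dG of ln s(G); positive on the healthy rising limb."""
    p = params
    rho = p.kIN / p.kRE
    rg = rho * p.g(G)
    dlnf = 2.0 * p.Kf ** 2 / (G * (G * G + p.Kf ** 2))
    dlng = 2.0 * p.Kg ** 2 / (G * (G * G + p.Kg ** 2))
    return dlnf - rg * dlng / (1.0 + rg)


def find_fixed_points(params: PatientParams, M: float = 0.0, FI: float = 0.0,
                      c: float | None = None,
                      polish: bool = True) -> list[FixedPoint]:
    """All physical fixed points of the death-free model at (M, FI).

    Roots of the steady-state polynomial are computed via the companion
    matrix; near-real roots (|imag| < 1e-6*(1+|real|)) with G in
    [0, 2000] mg/dL are kept, deduplicated within 1e-6 mg/dL, Newton-
    polished on the residual, and back-substituted into (I, beta, betaIN).
    Stability comes from the 4-state Jacobian with c frozen.
    """
    if c is None:
        c = params.cmax
    coeffs = fixed_point_polynomial(params, M, FI, c)
    if len(coeffs) < 2:
        return []
    # rescale G -> x*G_SCALE to balance coefficient magnitudes before the
    # companion-matrix eigenvalue solve
    G_SCALE = 100.0
    scaled = coeffs * (G_SCALE ** np.arange(len(coeffs)))
    scaled /= np.max(np.abs(scaled))
    roots = npoly.polyroots(scaled) * G_SCALE
    cand = sorted(
        float(r.real) for r in roots
        if abs(r.imag) < 1e-6 * (1.0 + abs(r.real))
        and -1e-9 <= r.real <= G_MAX_PHYSICAL
    )
    p = params
    out_G: list[float] = []
    for G in cand:
        G = max(G, 0.0)
        if polish and G > 0:
            for _ in range(30):
                r0 = steady_residual(G, p, M, FI, c)
                h = 1e-7 * (1.0 + G)
                dr = (steady_residual(G + h, p, M, FI, c)
                      - steady_residual(G - h, p, M, FI, c)) / (2.0 * h)
                if dr == 0:
                    break
                step = r0 / dr
                G_new = G - step
                if G_new <= 0:
                    G_new = G / 2.0
                if abs(G_new - G) < 1e-13 * (1.0 + abs(G)):
                    G = G_new
                    break
                G = G_new
        if any(abs(G - Gk) <= 1e-6 for Gk in out_G):
            continue
        # reject spurious roots that fail to satisfy the balance
        scale = p.m0 / p.I0 + abs(M) + p.SE * max(G, 1.0)
        if abs(steady_residual(G, p, M, FI, c)) > 1e-6 * scale:
            continue
        out_G.append(G)

    points = []
    for G in out_G:
        frac = 1.0 / (1.0 + (p.kIN / p.kRE) * p.g(G))
        beta = p.betaTOT * frac
        betaIN = p.betaTOT - beta
        I = (_secretion(p, G, c) + FI) / p.gamma
        y4 = np.array([G, I, beta, betaIN])
        eig = _stability_eigenvalues(y4, p, M, FI, c)
        points.append(dict(G=G, I=I, beta=beta, betaIN=betaIN,
                           stable=bool(np.all(eig.real < 0)), eig=eig))

    points.sort(key=lambda d: d["G"])
    n = len(points)
    fps = []
    for i, d in enumerate(points):
        if n >= 3:
            branch = ("high_beta", "intermediate", "low_beta")[min(i, 2)]
        elif n == 2:
            branch = "high_beta" if i == 0 else "low_beta"
        else:
            branch = ("high_beta" if _secretion_slope_sign(p, d["G"]) > 0
                      else "low_beta")
        fps.append(FixedPoint(
            G=d["G"], I=d["I"], beta=d["beta"], betaIN=d["betaIN"], c=c,
            stable=d["stable"], eigenvalues=tuple(d["eig"]), branch=branch))
    return fps


# ---------------------------------------------------------------------------
# bifurcation scans


@dataclass
class BifurcationScan:
    """Fixed-point branches along a one-parameter sweep."""

    knob: str
    values: np.ndarray
    points: list  # list (per knob value) of lists of FixedPoint
    bifurcations: list  # knob values where the stable-point count changes

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(fp.stable for fp in pts) for pts in self.points])

    def to_dataframe(self):
        import pandas as pd
        rows = []
        for v, pts in zip(self.values, self.points):
            for fp in pts:
                rows.append({self.knob: v, "G": fp.G, "I": fp.I,
                             "beta_frac": fp.beta / (fp.beta + fp.betaIN),
                             "stable": fp.stable, "branch": fp.branch})
        return pd.DataFrame(rows)


_KNOBS = ("M", "FI", "SI", "betaTOT", "kIN_over_kRE")


def _eval_at_knob(params: PatientParams, knob: str, value: float,
                  M: float, FI: float, c: float | None):
    if knob == "M":
        return find_fixed_points(params, value, FI, c)
    if knob == "FI":
        return find_fixed_points(params, M, value, c)
    if knob == "SI":
        return find_fixed_points(params.replace(SI=value), M, FI, c)
    if knob == "betaTOT":
        return find_fixed_points(params.replace(betaTOT=value), M, FI, c)
    if knob == "kIN_over_kRE":
        return find_fixed_points(
            params.replace(kIN=value * params.kRE), M, FI, c)
    raise ValueError(f"unknown knob {knob!r}; expected one of {_KNOBS}")


def scan_bifurcation(params: PatientParams, knob: str, grid,
                     M: float = 0.0, FI: float = 0.0,
                     c: float | None = None,
                     refine_rtol: float = 1e-4) -> BifurcationScan:
    """Sweep one knob over a monotone grid and locate saddle-node points.

    At every grid value the full fixed-point set is computed; knob intervals
    across which the count of *stable* points changes are refined by
    bisection to ``refine_rtol`` relative accuracy and reported as
    bifurcation points.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or not (
            np.all(np.diff(grid) > 0) or np.all(np.diff(grid) < 0)):
        raise ValueError("grid must be a monotone 1-D sequence")
    points = [_eval_at_knob(params, knob, v, M, FI, c) for v in grid]
    counts = [sum(fp.stable for fp in pts) for pts in points]

    bifs = []
    for i in range(len(grid) - 1):
        if counts[i] == counts[i + 1]:
            continue
        lo, hi = grid[i], grid[i + 1]
        n_lo = counts[i]
        while abs(hi - lo) > refine_rtol * (abs(lo) + abs(hi) + 1e-12):
            mid = 0.5 * (lo + hi)
            n_mid = sum(fp.stable for fp in
                        _eval_at_knob(params, knob, mid, M, FI, c))
            if n_mid == n_lo:
                lo = mid
            else:
                hi = mid
        bifs.append(0.5 * (lo + hi))
    return BifurcationScan(knob=knob, values=grid, points=points,
                           bifurcations=bifs)


# ---------------------------------------------------------------------------
# regime classification and the (SI, betaTOT) phase diagram


def _adapted_c(params: PatientParams) -> float:
    """Per-cell capacity c putting the meal-free healthy fixed point at G0."""
    from .calibration import fasting_insulin, quasi_steady_beta_fraction
    p = params
    I_star = fasting_insulin(p, p.G0)
    frac = quasi_steady_beta_fraction(p, p.G0)
    return float(p.gamma * I_star / (p.betaTOT * frac * p.f(p.G0)))


def classify_regime(params: PatientParams) -> RegimeClassification:
    """Classify the meal-free fixed-point structure of one parameter set.

    Solves at M = FI = 0 with c = cmax.  If the healthy branch lands below
    the adaptation target G0, secretory capacity is no longer saturated: c
    is reduced so that fasting glucose sits exactly at G0 and the structure
    is re-solved at that c.  The reported minimum fasting glucose is
    floored at G0 accordingly.
    """
    fps = find_fixed_points(params)
    stable = [fp for fp in fps if fp.stable]
    adapted = None
    if stable and min(fp.G for fp in stable) < params.G0:
        c_ad = _adapted_c(params)
        if c_ad < params.cmax:
            adapted = c_ad
            fps = find_fixed_points(params, c=c_ad)
            stable = [fp for fp in fps if fp.stable]

    if not stable:
        return RegimeClassification("monostable_low_beta", float("nan"),
                                    fps, adapted)
    min_G = max(min(fp.G for fp in stable), params.G0)
    if len(stable) >= 2:
        regime = "bistable"
    else:
        regime = ("monostable_high_beta" if stable[0].branch == "high_beta"
                  else "monostable_low_beta")
    return RegimeClassification(regime, float(min_G), fps, adapted)


@dataclass
class PhaseDiagram:
    """Regime classification over a grid of relative (SI, betaTOT) scalings."""

    SI_rel: np.ndarray
    betaTOT_rel: np.ndarray
    regime: np.ndarray          # (len(betaTOT_rel), len(SI_rel)) of str
    min_fasting_G: np.ndarray   # same shape, mg/dL
    base_params: PatientParams = field(repr=False, default=None)

    def to_dataframe(self):
        import pandas as pd
        SI, BT = np.meshgrid(self.SI_rel, self.betaTOT_rel)
        return pd.DataFrame({
            "SI_rel": SI.ravel(), "betaTOT_rel": BT.ravel(),
            "regime": self.regime.ravel(),
            "min_fasting_G": self.min_fasting_G.ravel(),
        })


def phase_diagram(params: PatientParams, SI_grid=None,
                  betaTOT_grid=None) -> PhaseDiagram:
    """Classify the regime over a (SI, betaTOT) grid of relative scalings.

    Grids are multiplicative factors applied to ``params.SI`` and
    ``params.betaTOT``; defaults span [0.25, 2] at 101 points each.
    """
    if SI_grid is None:
        SI_grid = np.linspace(0.25, 2.0, 101)
    if betaTOT_grid is None:
        betaTOT_grid = np.linspace(0.25, 2.0, 101)
    SI_grid = np.asarray(SI_grid, dtype=float)
    betaTOT_grid = np.asarray(betaTOT_grid, dtype=float)
    if np.any(SI_grid <= 0) or np.any(betaTOT_grid <= 0):
        raise ValueError("phase-diagram grids must be positive")
    regime = np.empty((len(betaTOT_grid), len(SI_grid)), dtype=object)
    minG = np.empty_like(regime, dtype=float)
    for i, bt in enumerate(betaTOT_grid):
        for j, si in enumerate(SI_grid):
            cls = classify_regime(params.replace(
                SI=params.SI * si, betaTOT=params.betaTOT * bt))
            regime[i, j] = cls.regime
            minG[i, j] = cls.min_fasting_G
    return PhaseDiagram(SI_grid, betaTOT_grid, regime, minG, params)
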