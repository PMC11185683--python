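"""Multi-phase scenario integration of the full five-state model.

A scenario is an ordered list of phases, each with a meal schedule and an
insulin protocol (none, constant flux, or target-glucose titration).  The
system is stiff — insulin turns over at ~432/day while beta-cell death
runs at ~1e-3/day — so integration uses an implicit adaptive-step method
(Radau by default), split at every meal-pulse edge and day boundary so the
discontinuous meal flux never crosses a solver step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import PatientParams, PhysioState, rhs_array
from . import equilibria

__all__ = [
    "MealSchedule",
    "InsulinProtocol",
    "Phase",
    "ScenarioTimeline",
    "Trajectory",
    "integrate",
    "daily_average",
    "classify_state",
    "run_phenotype_scenario",
    "healthy_initial_state",
]

#: Canonical meal times as fractions of the day (08:00, 13:00, 19:00).
DEFAULT_MEAL_TIMES = (8.0 / 24.0, 13.0 / 24.0, 19.0 / 24.0)


@dataclass(frozen=True)
class MealSchedule:
    """Rectangular meal pulses: daily_total spread over meals_per_day pulses.

    Each pulse lasts ``meal_duration`` days (default 30 min) and carries an
    equal share of ``daily_total`` (mg/dL/day integrated over the day), so
    the flux during a pulse is daily_total / (meals_per_day*meal_duration).
    """

    daily_total: float = 0.0
    meals_per_day: int = 3
    meal_duration: float = 1.0 / 48.0
    meal_times: tuple = DEFAULT_MEAL_TIMES

    def __post_init__(self):
        if self.daily_total < 0:
            raise ValueError("daily_total must be >= 0")
        if self.daily_total > 0:
            if len(self.meal_times) != self.meals_per_day:
                raise ValueError("need one meal time per meal")
            if self.meals_per_day * self.meal_duration > 1.0:
                raise ValueError("meals overlap the day")

    @property
    def pulse_flux(self) -> float:
        """Glucose flux during a pulse, mg/dL/day."""
        if self.daily_total == 0:
            return 0.0
        return self.daily_total / (self.meals_per_day * self.meal_duration)

    def flux_at(self, t: float) -> float:
        """Meal flux at absolute time t (days)."""
        if self.daily_total == 0:
            return 0.0
        tod = t % 1.0
        for t0 in self.meal_times:
            if t0 <= tod < t0 + self.meal_duration:
                return self.pulse_flux
        return 0.0

    def edges_in(self, t0: float, t1: float) -> list[float]:
        """Pulse start/end times falling strictly inside (t0, t1)."""
        if self.daily_total == 0:
            return []
        edges = []
        day = int(np.floor(t0))
        while day <= int(np.floor(t1)):
            for tm in self.meal_times:
                for e in (day + tm, day + tm + self.meal_duration):
                    if t0 < e < t1:
                        edges.append(e)
            day += 1
        return sorted(edges)


@dataclass(frozen=True)
class InsulinProtocol:
    """Exogenous insulin policy for one phase.

    mode "none": FI = 0 throughout.
    mode "constant_flux": FI held at ``FI`` (uU/mL/day).
    mode "titrated": FI piecewise-constant, re-titrated every
    ``update_interval`` days by the multiplicative rule
    FI <- FI * (daily-mean G / target_G), the factor clipped to [1/2, 2].
    """

    mode: str = "none"
    FI: float = 0.0
    target_G: float = 90.0
    update_interval: float = 3.0

    def __post_init__(self):
        if self.mode not in ("none", "constant_flux", "titrated"):
            raise ValueError(f"unknown insulin mode {self.mode!r}")
        if self.FI < 0:
            raise ValueError("FI must be >= 0")
        if self.mode == "titrated" and (self.target_G <= 0
                                        or self.update_interval <= 0):
            raise ValueError("titrated mode needs positive target and interval")


@dataclass(frozen=True)
class Phase:
    """One scenario phase: a duration with fixed meal and insulin policies."""

    duration: float
    meals: MealSchedule = MealSchedule()
    insulin: InsulinProtocol = InsulinProtocol()
    name: str = ""

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("phase duration must be > 0")


@dataclass(frozen=True)
class ScenarioTimeline:
    """Ordered phases executed back-to-back with state continuity."""

    phases: tuple

    def __post_init__(self):
        if not self.phases:
            raise ValueError("timeline needs at least one phase")

    @property
    def total_duration(self) -> float:
        return sum(ph.duration for ph in self.phases)


@dataclass
class Trajectory:
    """Sampled solution: time grid, states, phase labels and applied FI."""

    t: np.ndarray
    y: np.ndarray          # shape (n, 5): G, I, beta, betaIN, c
    phase: np.ndarray      # phase name per sample
    FI: np.ndarray         # exogenous insulin flux applied at each sample

    @property
    def G(self): return self.y[:, 0]

    @property
    def I(self): return self.y[:, 1]

    @property
    def beta(self): return self.y[:, 2]

    @property
    def betaIN(self): return self.y[:, 3]

    @property
    def c(self): return self.y[:, 4]

    def state_at_end(self) -> PhysioState:
        return PhysioState.from_array(self.y[-1])

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({
            "t_days": self.t, "G": self.G, "I": self.I, "beta": self.beta,
            "betaIN": self.betaIN, "c": self.c, "phase": self.phase,
            "FI": self.FI,
        })

    @classmethod
    def concatenate(cls, parts: list["Trajectory"]) -> "Trajectory":
        return cls(np.concatenate([p.t for p in parts]),
                   np.concatenate([p.y for p in parts]),
                   np.concatenate([p.phase for p in parts]),
                   np.concatenate([p.FI for p in parts]))


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last good state."""

    def __init__(self, message, t, state):
        super().__init__(message)
        self.t = t
        self.state = state


def _integrate_segment(params, y0, t0, t1, M, FI, rtol, atol, method,
                       samples_per_day):
    """Integrate over [t0, t1] with constant M and FI."""
    n_extra = max(int(np.ceil((t1 - t0) * samples_per_day)), 1)
    t_eval = np.linspace(t0, t1, n_extra + 1)
    sol = solve_ivp(lambda t, y: rhs_array(y, params, M, FI), (t0, t1), y0,
                    method=method, rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:
        raise IntegrationError(f"integrator failed at t={sol.t[-1]:.4f}: "
                               f"{sol.message}", sol.t[-1],
                               PhysioState.from_array(sol.y[:, -1]))
    # exact-arithmetic invariants (positivity, c <= cmax) can be violated
    # by solver-tolerance-sized overshoots; clip them away
    y = np.clip(sol.y.T, 0.0, None)
    y[:, 4] = np.minimum(y[:, 4], params.cmax)
    return sol.t, y


def _phase_breakpoints(phase: Phase, t0: float) -> list[tuple[float, float]]:
    """(start, end) sub-intervals of a phase split at meal edges and days."""
    t1 = t0 + phase.duration
    edges = set(phase.meals.edges_in(t0, t1))
    # day boundaries keep daily averages exact
    d = np.ceil(t0)
    while d < t1:
        if t0 < d < t1:
            edges.add(float(d))
        d += 1.0
    pts = [t0] + sorted(edges) + [t1]
    return [(pts[i], pts[i + 1]) for i in range(len(pts) - 1)]


def integrate(params: PatientParams, init: PhysioState,
              timeline: ScenarioTimeline, rtol: float = 1e-8,
              atol: float = 1e-10, method: str = "Radau",
              samples_per_day: int = 8) -> Trajectory:
    """Integrate the full model across all phases of a timeline.

    State is continuous across phase boundaries.  Within a phase the
    integration is split at every meal-pulse edge and day boundary, with
    constant exogenous fluxes inside each segment, so the solver never
    steps across a flux discontinuity.  Titrated insulin phases update FI
    every ``update_interval`` days from the preceding interval's
    time-weighted mean glucose.
    """
    init.validate(params)
    y = init.as_array().copy()
    t = 0.0
    parts = []
    for phase in timeline.phases:
        t_end = t + phase.duration
        proto = phase.insulin
        if proto.mode == "titrated":
            FI = proto.FI if proto.FI > 0 else _initial_titration_flux(
                params, y, proto.target_G)
            block_starts = np.arange(t, t_end, proto.update_interval)
            for bs in block_starts:
                be = min(bs + proto.update_interval, t_end)
                part = _run_span(params, y, bs, be, phase, FI, rtol, atol,
                                 method, samples_per_day)
                parts.append(part)
                y = part.y[-1].copy()
                mean_G = np.trapezoid(part.G, part.t) / (part.t[-1] - part.t[0])
                FI = float(np.clip(FI * np.clip(mean_G / proto.target_G,
                                                0.5, 2.0), 0.0, None))
        else:
            FI = proto.FI if proto.mode == "constant_flux" else 0.0
            part = _run_span(params, y, t, t_end, phase, FI, rtol, atol,
                             method, samples_per_day)
            parts.append(part)
            y = part.y[-1].copy()
        t = t_end
    return Trajectory.concatenate(parts)


def _run_span(params, y0, t0, t1, phase: Phase, FI, rtol, atol, method,
              samples_per_day) -> Trajectory:
    """Integrate [t0, t1] of one phase at fixed FI, honouring meal pulses."""
    sub = Phase(duration=t1 - t0, meals=phase.meals, insulin=phase.insulin,
                name=phase.name)
    ts, ys = [], []
    y = np.asarray(y0, dtype=float).copy()
    for (a, b) in _phase_breakpoints(sub, t0):
        M = phase.meals.flux_at(0.5 * (a + b))
        seg_t, seg_y = _integrate_segment(params, y, a, b, M, FI, rtol, atol,
                                          method, samples_per_day)
        y = seg_y[-1].copy()
        if ts:  # drop duplicated segment-start sample
            seg_t, seg_y = seg_t[1:], seg_y[1:]
        ts.append(seg_t)
        ys.append(seg_y)
    t = np.concatenate(ts)
    yy = np.vstack(ys)
    return Trajectory(t, yy, np.full(len(t), phase.name, dtype=object),
                      np.full(len(t), float(FI)))


def untreated_fasting_G(state: PhysioState, params: PatientParams) -> float:
    """Fasting glucose the patient would settle at if insulin stopped now.

    Holds the slow variables (beta, c) at their current values and solves
    the fast-subsystem steady state: m0/(I0+I(G)) = G*(SE+SI*I(G)) with
    I(G) = beta*c*f(G)/gamma.  The residual is strictly decreasing in G,
    so the root is unique.
    """
    from scipy.optimize import brentq
    p = params

    def resid(G):
        I = state.beta * state.c * p.f(G) / p.gamma
        return p.m0 / (p.I0 + I) - (p.SE + p.SI * I) * G

    if resid(equilibria.G_MAX_PHYSICAL) > 0:
        return equilibria.G_MAX_PHYSICAL
    return float(brentq(resid, 1e-6, equilibria.G_MAX_PHYSICAL, xtol=1e-8))


def _initial_titration_flux(params, y, target_G) -> float:
    """Starting insulin flux for titration: the clamp balance at current beta."""
    from .treatment import clamp_insulin
    I_star = clamp_insulin(target_G, params)
    secretion = y[2] * y[4] * params.f(target_G)
    return float(max(params.gamma * I_star - secretion, 0.0))


def daily_average(traj: Trajectory, column: str = "G"):
    """Time-weighted mean of one state column over each calendar day.

    Returns (day_start_times, means); days not fully covered at the ends of
    the trajectory are averaged over the covered portion.
    """
    if len(traj.t) < 2:
        raise ValueError("trajectory too short for daily averages")
    vals = getattr(traj, column)
    t = traj.t
    first, last = int(np.floor(t[0])), int(np.ceil(t[-1]))
    days, means = [], []
    for d in range(first, last):
        m = (t >= d) & (t <= d + 1)
        if m.sum() < 2:
            continue
        td, vd = t[m], vals[m]
        span = td[-1] - td[0]
        if span <= 0:
            continue
        days.append(d)
        means.append(float(np.trapezoid(vd, td) / span))
    if not days:
        raise ValueError("trajectory spans less than one day")
    return np.array(days, dtype=float), np.array(means)


def unstable_beta_threshold(params: PatientParams) -> float | None:
    """beta of the meal-free unstable fixed point, or None if monostable."""
    fps = equilibria.find_fixed_points(params)
    for fp in fps:
        if not fp.stable and fp.branch == "intermediate":
            return fp.beta
    return None


def classify_state(state: PhysioState, params: PatientParams):
    """Basin label for a state: which fixed point it would relax toward.

    Glucose dynamics are fast, so the meal-free unstable fixed point's beta
    acts as the basin threshold: beta above it flows to the healthy high-
    beta state, beta at or below it to the hyperglycemic state (boundary
    classified hyperglycemic).  In a monostable regime every state is in
    the healthy basin; the second return value flags that case.

    Returns
    -------
    (label, monostable) : (str, bool)
        label in {"healthy_basin", "hyperglycemic_basin"}.
    """
    thr = unstable_beta_threshold(params)
    if thr is None:
        return "healthy_basin", True
    return (("healthy_basin", False) if state.beta > thr
            else ("hyperglycemic_basin", False))


def healthy_initial_state(params: PatientParams) -> PhysioState:
    """The meal-free healthy stable fixed point with c = cmax.

    The canonical starting condition: a patient in advanced prediabetes
    whose secretory adaptation is already saturated.
    """
    fps = [fp for fp in equilibria.find_fixed_points(params) if fp.stable]
    if not fps:
        raise ValueError("no stable fixed point to start from")
    fp = min(fps, key=lambda q: q.G)
    return PhysioState(G=fp.G, I=fp.I, beta=fp.beta, betaIN=fp.betaIN,
                       c=params.cmax)


# ---------------------------------------------------------------------------
# canonical phenotype scenarios


def run_phenotype_scenario(phenotype: str | PatientParams,
                           baseline_days: float = 60.0,
                           high_sugar_days: float = 30.0,
                           followup_days: float = 120.0,
                           treat: bool | None = None,
                           target_G: float = 90.0,
                           max_treatment_days: float = 180.0,
                           rtol: float = 1e-8, atol: float = 1e-10,
                           samples_per_day: int = 8):
    """Run the canonical onset/treatment/remission scenario for one patient.

    Baseline meals carry 3% of the fasting hepatic glucose production, the
    high-sugar month 70%.  If ``treat`` (default: automatic — treatment is
    given when the high-sugar month has pushed the patient into the
    hyperglycemic basin), titrated insulin is applied in 3-day blocks until
    the healthy basin is re-entered and daily glucose is controlled, up to
    ``max_treatment_days``; a follow-up phase then runs without insulin.

    Returns (trajectory, summary_dict).
    """
    from .calibration import phenotype_presets, meal_budget

    if isinstance(phenotype, str):
        params = phenotype_presets()[phenotype]
        label = phenotype
    else:
        params = phenotype
        label = "custom"

    normal_meals = MealSchedule(daily_total=meal_budget(0.03, params))
    sugar_meals = MealSchedule(daily_total=meal_budget(0.70, params))
    init = healthy_initial_state(params)
    thr = unstable_beta_threshold(params)

    kw = dict(rtol=rtol, atol=atol, samples_per_day=samples_per_day)
    parts = []
    traj = integrate(params, init, ScenarioTimeline((
        Phase(baseline_days, normal_meals, name="baseline"),
        Phase(high_sugar_days, sugar_meals, name="high_sugar"),
    )), **kw)
    parts.append(traj)
    state = traj.state_at_end()

    in_hyper = (thr is not None and state.beta <= thr)
    if treat is None:
        treat = in_hyper

    summary = {
        "phenotype": label,
        "onset_day": _first_crossing_day(traj, thr),
        "treated": bool(treat),
        "treatment_days": 0.0,
        "remission": None,
        "relapse_day": None,
    }

    t_now = baseline_days + high_sugar_days
    if treat:
        titration_interval = 3.0
        FI = _initial_titration_flux(params, state.as_array(), target_G)
        treated = 0.0
        since_titration = 0.0
        mean_Gs = []
        # 1-day blocks: titrate every 3 days, but check daily whether the
        # patient could hold G <= 130 mg/dL without insulin ("well
        # controlled"), so treatment ends as soon as remission is secured
        while treated < max_treatment_days:
            part = integrate(
                params, state,
                ScenarioTimeline((Phase(1.0, normal_meals,
                                        InsulinProtocol("constant_flux", FI=FI),
                                        name="treatment"),)), **kw)
            part = Trajectory(part.t + t_now, part.y, part.phase, part.FI)
            parts.append(part)
            state = part.state_at_end()
            t_now += 1.0
            treated += 1.0
            since_titration += 1.0
            mean_Gs.append(np.trapezoid(part.G, part.t)
                           / (part.t[-1] - part.t[0]))
            if since_titration >= titration_interval:
                mean_G = float(np.mean(mean_Gs[-int(titration_interval):]))
                FI = float(np.clip(FI * np.clip(mean_G / target_G, 0.5, 2.0),
                                   0.0, None))
                since_titration = 0.0
            basin, _ = classify_state(state, params)
            if (basin == "healthy_basin"
                    and untreated_fasting_G(state, params) <= 130.0):
                break
        summary["treatment_days"] = treated

    tail = integrate(params, state, ScenarioTimeline((
        Phase(followup_days, normal_meals, name="followup"),)), **kw)
    tail = Trajectory(tail.t + t_now, tail.y, tail.phase, tail.FI)
    parts.append(tail)

    traj_all = Trajectory.concatenate(parts)
    end_state = traj_all.state_at_end()
    basin_end, _ = classify_state(end_state, params)
    days, means = daily_average(traj_all)
    final_mean_G = float(means[-1])
    summary["remission"] = bool(basin_end == "healthy_basin"
                                and final_mean_G <= 130.0)
    summary["final_daily_G"] = final_mean_G
    summary["final_beta_total"] = float(end_state.beta + end_state.betaIN)
    if treat and not summary["remission"]:
        summary["relapse_day"] = _first_crossing_day(tail, thr)
    return traj_all, summary


def _first_crossing_day(traj: Trajectory, thr: float | None):
    """First time beta drops to or below the basin threshold, else None."""
    if thr is None:
        return None
    below = traj.beta <= thr
    if not below.any():
        return None
    return float(traj.t[int(np.argmax(below))])
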