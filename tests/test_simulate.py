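"""Scenario integration, daily averages, basin classification."""

import numpy as np
import pytest

from kpdsim import equilibria as eq
from kpdsim import simulate as sim
from kpdsim.model_core import PhysioState


@pytest.fixture(scope="module")
def B_no_death(preset_B):
    return preset_B.replace(kD=0.0)


class TestMealSchedule:
    def test_daily_integral_equals_budget(self):
        ms = sim.MealSchedule(daily_total=480.0)
        t = np.linspace(0.0, 1.0, 200001)
        flux = np.array([ms.flux_at(x) for x in t])
        assert np.trapezoid(flux, t) == pytest.approx(480.0, rel=1e-3)

    def test_edges_bracket_each_pulse(self):
        ms = sim.MealSchedule(daily_total=100.0)
        edges = ms.edges_in(0.0, 1.0)
        assert len(edges) == 6  # 3 pulses x (start, end)
        assert np.allclose(np.diff(edges)[::2], ms.meal_duration)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sim.MealSchedule(daily_total=-1.0)
        with pytest.raises(ValueError):
            sim.MealSchedule(daily_total=10.0, meals_per_day=2)


class TestIntegrate:
    def test_fixed_point_is_held(self, B_no_death):
        # meal-free, insulin-free start exactly at the healthy fixed point:
        # nothing should move
        init = sim.healthy_initial_state(B_no_death)
        tl = sim.ScenarioTimeline((sim.Phase(30.0, name="hold"),))
        traj = sim.integrate(B_no_death, init, tl)
        assert np.max(np.abs(traj.G - init.G)) < 1e-3 * init.G
        assert np.max(np.abs(traj.beta - init.beta)) < 1e-3 * init.beta

    def test_pool_conservation_without_death(self, B_no_death):
        init = sim.healthy_initial_state(B_no_death)
        tl = sim.ScenarioTimeline((
            sim.Phase(5.0, sim.MealSchedule(daily_total=500.0), name="sugar"),
            sim.Phase(5.0, insulin=sim.InsulinProtocol("constant_flux",
                                                       FI=1000.0),
                      name="insulin"),
        ))
        traj = sim.integrate(B_no_death, init, tl)
        total = traj.beta + traj.betaIN
        assert np.max(np.abs(total - B_no_death.betaTOT)) < 1e-8

    def test_positivity(self, preset_B):
        init = sim.healthy_initial_state(preset_B)
        tl = sim.ScenarioTimeline((
            sim.Phase(3.0, sim.MealSchedule(daily_total=500.0),
                      name="sugar"),))
        traj = sim.integrate(preset_B, init, tl)
        assert np.all(traj.y >= -1e-12)

    def test_converges_to_analytic_fixed_point(self, B_no_death):
        # oracle equivalence: a start near the healthy fixed point relaxes
        # onto it to better than 0.1 mg/dL
        fps = [fp for fp in eq.find_fixed_points(B_no_death) if fp.stable]
        for fp in fps:
            init = PhysioState(G=fp.G * 1.02, I=fp.I, beta=fp.beta * 1.02,
                               betaIN=B_no_death.betaTOT - fp.beta * 1.02,
                               c=B_no_death.cmax)
            tl = sim.ScenarioTimeline((sim.Phase(400.0, name="relax"),))
            traj = sim.integrate(B_no_death, init, tl, samples_per_day=1)
            assert abs(traj.G[-1] - fp.G) < 0.1

    def test_phase_labels_and_continuity(self, B_no_death):
        init = sim.healthy_initial_state(B_no_death)
        tl = sim.ScenarioTimeline((
            sim.Phase(1.0, name="one"),
            sim.Phase(1.0, sim.MealSchedule(daily_total=100.0), name="two")))
        traj = sim.integrate(B_no_death, init, tl)
        assert set(traj.phase) == {"one", "two"}
        assert np.all(np.diff(traj.t) >= 0)


class TestDailyAverage:
    def _flat_traj(self, levels):
        ts, Gs = [], []
        for d, level in enumerate(levels):
            t = np.linspace(d, d + 1, 25)
            ts.append(t)
            Gs.append(np.full_like(t, float(level)))
        t = np.concatenate(ts)
        y = np.zeros((len(t), 5))
        y[:, 0] = np.concatenate(Gs)
        return sim.Trajectory(t, y, np.full(len(t), "p", dtype=object),
                              np.zeros(len(t)))

    def test_piecewise_constant_days(self):
        days, means = sim.daily_average(self._flat_traj([100.0, 120.0]))
        assert np.allclose(means, [100.0, 120.0])

    def test_constant_glucose(self):
        _, means = sim.daily_average(self._flat_traj([110.0] * 3))
        assert np.allclose(means, 110.0)

    def test_too_short_trajectory_rejected(self):
        t = np.array([0.0])
        traj = sim.Trajectory(t, np.zeros((1, 5)),
                              np.array(["p"], dtype=object), np.zeros(1))
        with pytest.raises(ValueError):
            sim.daily_average(traj)


class TestClassifyState:
    def test_threshold_decides_basin(self, preset_B):
        thr = sim.unstable_beta_threshold(preset_B)
        assert thr is not None
        above = PhysioState(G=200.0, I=3.0, beta=thr * 1.05,
                            betaIN=1 - thr * 1.05, c=preset_B.cmax)
        below = PhysioState(G=200.0, I=3.0, beta=thr * 0.95,
                            betaIN=1 - thr * 0.95, c=preset_B.cmax)
        at = PhysioState(G=200.0, I=3.0, beta=thr, betaIN=1 - thr,
                         c=preset_B.cmax)
        assert sim.classify_state(above, preset_B) == ("healthy_basin", False)
        assert sim.classify_state(below, preset_B) == (
            "hyperglycemic_basin", False)
        # boundary convention: the threshold itself is hyperglycemic
        assert sim.classify_state(at, preset_B)[0] == "hyperglycemic_basin"

    def test_monostable_regime_is_flagged(self, preset_A):
        s = PhysioState(G=300.0, I=2.0, beta=0.01, betaIN=0.99,
                        c=preset_A.cmax)
        label, mono = sim.classify_state(s, preset_A)
        assert label == "healthy_basin" and mono

    def test_untreated_fasting_G_at_fixed_point(self, preset_B):
        init = sim.healthy_initial_state(preset_B)
        assert sim.untreated_fasting_G(init, preset_B) == pytest.approx(
            110.0, abs=0.1)


class TestScaledScenario:
    """A shortened high-sugar challenge showing the basin contrast."""

    def test_KPD_patient_switches_but_not_conventional(self, preset_A,
                                                       preset_B):
        from kpdsim.calibration import meal_budget
        for params, expect_switch in ((preset_A, False), (preset_B, True)):
            init = sim.healthy_initial_state(params)
            tl = sim.ScenarioTimeline((
                sim.Phase(5.0, sim.MealSchedule(
                    daily_total=meal_budget(0.03, params)), name="baseline"),
                sim.Phase(30.0, sim.MealSchedule(
                    daily_total=meal_budget(0.70, params)), name="sugar"),
            ))
            traj = sim.integrate(params, init, tl, rtol=1e-6, atol=1e-8)
            basin, _ = sim.classify_state(traj.state_at_end(), params)
            switched = basin == "hyperglycemic_basin"
            assert switched == expect_switch
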