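"""Fixed-point solver, stability, bifurcation scans, regime classification."""

import numpy as np
import pytest
from scipy.optimize import brentq

from kpdsim import equilibria as eq
from kpdsim.model_core import PatientParams


def bisection_roots(params, M=0.0, FI=0.0, c=None, G_hi=2000.0, n_grid=8000):
    """Independent oracle: sign-change bisection on the steady-state residual."""
    G = np.linspace(1e-3, G_hi, n_grid)
    r = eq.steady_residual(G, params, M, FI, c)
    roots = []
    for i in np.nonzero(np.sign(r[:-1]) * np.sign(r[1:]) < 0)[0]:
        roots.append(brentq(eq.steady_residual, G[i], G[i + 1],
                            args=(params, M, FI, c), xtol=1e-10))
    return np.array(roots)


class TestFixedPointPolynomial:
    def test_roots_satisfy_residual(self, preset_B):
        for fp in eq.find_fixed_points(preset_B):
            scale = preset_B.m0 / preset_B.I0
            assert abs(eq.steady_residual(fp.G, preset_B)) < 1e-9 * scale

    def test_degree_at_most_nine(self, preset_B):
        coeffs = eq.fixed_point_polynomial(preset_B, M=50.0, FI=30.0)
        assert 2 <= len(coeffs) <= 10

    def test_no_feedback_special_case(self):
        # with SI = 0 and kIN = 0 the balance reduces to
        # m0/(Q*f(G)/gamma + I0) + M = SE*G; check against bisection
        p = PatientParams(SI=1e-12, kIN=1e-12)
        got = sorted(fp.G for fp in eq.find_fixed_points(p, M=100.0))
        want = bisection_roots(p, M=100.0)
        assert np.allclose(got, want, atol=1e-6)

    def test_matches_bisection_oracle_on_random_draws(self, presets):
        # companion-matrix roots == residual-bisection roots to 1e-6 mg/dL
        rng = np.random.default_rng(42)
        bases = [presets["A"], presets["B"]]
        for k in range(25):
            base = bases[k % 2]
            fac = rng.uniform(0.8, 1.25, size=6)
            p = base.replace(SI=base.SI * fac[0], SE=base.SE * fac[1],
                             kIN=base.kIN * fac[2], kRE=base.kRE * fac[3],
                             cmax=base.cmax * fac[4],
                             betaTOT=base.betaTOT * fac[5])
            M, FI = rng.uniform(0, 300), rng.uniform(0, 1000)
            got = np.array(sorted(fp.G for fp in
                                  eq.find_fixed_points(p, M, FI)))
            want = bisection_roots(p, M, FI)
            assert len(got) == len(want), (k, got, want)
            assert np.allclose(got, want, atol=1e-6)


class TestFindFixedPoints:
    def test_preset_A_is_monostable(self, preset_A):
        fps = eq.find_fixed_points(preset_A)
        assert len(fps) == 1
        assert fps[0].stable
        assert fps[0].G == pytest.approx(110.0, abs=0.1)

    def test_preset_B_is_bistable(self, preset_B):
        fps = eq.find_fixed_points(preset_B)
        assert len(fps) == 3
        assert [fp.stable for fp in fps] == [True, False, True]
        assert [fp.branch for fp in fps] == ["high_beta", "intermediate",
                                             "low_beta"]
        # quasi-steady active fraction at each steady glucose
        for fp in fps:
            frac = 1 / (1 + (preset_B.kIN / preset_B.kRE) * preset_B.g(fp.G))
            assert fp.beta == pytest.approx(preset_B.betaTOT * frac)

    def test_large_M_leaves_only_hyperglycemic_point(self, preset_B):
        fps = eq.find_fixed_points(preset_B, M=600.0)
        assert len(fps) == 1
        assert fps[0].stable and fps[0].branch == "low_beta"

    def test_large_FI_leaves_only_healthy_point(self, preset_B):
        fps = eq.find_fixed_points(preset_B, FI=3000.0)
        assert len(fps) == 1
        assert fps[0].stable and fps[0].branch == "high_beta"
        frac = 1 / (1 + (preset_B.kIN / preset_B.kRE) * preset_B.g(fps[0].G))
        assert fps[0].beta / preset_B.betaTOT == pytest.approx(frac)

    def test_stable_count_is_odd_with_alternation(self, presets):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = presets["B"].replace(
                kIN=presets["B"].kIN * rng.uniform(0.3, 3.0),
                SI=presets["B"].SI * rng.uniform(0.5, 2.0))
            fps = eq.find_fixed_points(p)
            if not fps:
                continue
            stabs = [fp.stable for fp in fps]
            assert sum(stabs) in (1, 2)
            # stability alternates along increasing G
            assert all(a != b for a, b in zip(stabs, stabs[1:]))


class TestBifurcationScans:
    def test_meal_flux_saddle_node(self, preset_B):
        scan = eq.scan_bifurcation(preset_B, "M", np.linspace(0, 600, 31))
        counts = scan.stable_counts()
        assert counts[0] == 2 and counts[-1] == 1
        assert len(scan.bifurcations) == 1
        assert 0 < scan.bifurcations[0] < 600

    def test_insulin_flux_restores_monostability(self, preset_B):
        scan = eq.scan_bifurcation(preset_B, "FI", np.linspace(0, 3000, 31))
        counts = scan.stable_counts()
        assert counts[0] == 2 and counts[-1] == 1
        assert scan.points[-1][0].branch == "high_beta"

    def test_inactivation_ratio_window(self, preset_A):
        # bistability exists only in a window of kIN/kRE; none below it
        grid = np.geomspace(30.0, 3e4, 41)
        scan = eq.scan_bifurcation(preset_A, "kIN_over_kRE", grid)
        counts = scan.stable_counts()
        bist = np.nonzero(counts == 2)[0]
        assert len(bist) > 0
        assert counts[0] == 1 and np.all(counts[:bist[0]] == 1)

    def test_insulin_sensitivity_destroys_low_beta_point(self, preset_B):
        scan = eq.scan_bifurcation(preset_B, "SI",
                                   np.linspace(preset_B.SI, 3 * preset_B.SI,
                                               21))
        counts = scan.stable_counts()
        assert counts[0] == 2 and counts[-1] == 1
        assert scan.points[-1][0].branch == "high_beta"

    def test_monotone_grid_required(self, preset_B):
        with pytest.raises(ValueError):
            eq.scan_bifurcation(preset_B, "M", [0.0, 2.0, 1.0])


class TestRegimeClassification:
    def test_preset_regimes(self, preset_A, preset_B):
        a = eq.classify_regime(preset_A)
        assert a.regime == "monostable_high_beta"
        assert a.min_fasting_G == pytest.approx(110.0, abs=0.1)
        b = eq.classify_regime(preset_B)
        assert b.regime == "bistable"
        assert b.min_fasting_G == pytest.approx(110.0, abs=0.1)

    def test_depleted_beta_pool_gives_insulin_dependence(self, preset_B):
        cls = eq.classify_regime(preset_B.replace(betaTOT=0.3))
        assert cls.regime == "monostable_low_beta"

    def test_adaptation_floors_fasting_glucose(self, preset_B):
        # ample secretory reserve would push G below the 80 mg/dL target;
        # adaptation backs c off cmax and fasting G floors at 80
        cls = eq.classify_regime(preset_B.replace(betaTOT=3.0,
                                                  SI=2 * preset_B.SI))
        assert cls.min_fasting_G == pytest.approx(80.0)
        assert cls.adapted_c is not None
        assert cls.adapted_c < preset_B.cmax
        assert cls.regime == "monostable_high_beta"


class TestPhaseDiagram:
    def test_all_three_regimes_for_KPD_parameters(self, preset_B):
        grid = np.linspace(0.25, 2.0, 13)
        pd_ = eq.phase_diagram(preset_B, grid, grid)
        found = set(pd_.regime.ravel())
        assert {"monostable_high_beta", "bistable",
                "monostable_low_beta"} <= found

    def test_no_bistability_for_low_inactivation(self, preset_A):
        grid = np.linspace(0.25, 2.0, 9)
        pd_ = eq.phase_diagram(preset_A, grid, grid)
        assert "bistable" not in set(pd_.regime.ravel())

    def test_normal_fasting_glucose_protects(self, preset_B):
        grid = np.linspace(0.25, 2.0, 13)
        pd_ = eq.phase_diagram(preset_B, grid, grid)
        floored = pd_.min_fasting_G == pytest.approx(80.0)
        assert np.all(pd_.regime[floored] == "monostable_high_beta")

    def test_positive_grids_required(self, preset_B):
        with pytest.raises(ValueError):
            eq.phase_diagram(preset_B, [-1.0, 1.0], [1.0])
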