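# Methods

## The model

`kpdsim` implements a mechanistic model of glucose regulation in
ketosis-prone type 2 diabetes (KPD), a phenotype that presents like
type 1 diabetes — abrupt severe hyperglycemia, often with ketoacidosis —
yet typically remits to insulin independence after weeks of insulin
therapy.  The model's central hypothesis is that, on top of the
well-established slow irreversible loss of pancreatic beta-cells, KPD-prone
patients carry a *fast, reversible* glucotoxic inactivation of beta-cells.
That reversible step closes a positive feedback loop (high glucose →
fewer active beta-cells → less insulin → higher glucose) and turns fasting
glucose into a toggle switch with two stable states.

State variables (units: mg/dL, μU/mL, days):

| symbol | meaning |
|---|---|
| G | plasma glucose |
| I | plasma insulin |
| β | active beta-cell mass (dimensionless, β_TOT = 1) |
| β_IN | reversibly inactivated beta-cell mass |
| c | per-cell secretory capacity, ≤ c_max |

Dynamics:

    dG/dt    = M(t) + m0/(I0 + I) − (SE + SI·I)·G
    dI/dt    = β·c·f(G) + FI(t) − γ·I
    dβ/dt    = −[kIN·g(G) + kD·h(G)]·β + kRE·β_IN
    dβ_IN/dt = −[kRE + kD·h(G)]·β_IN + kIN·g(G)·β
    dc/dt    = a(G_f − G0, c)

with f, g, h order-2 Hill functions of glucose (midpoints Kf, Kg, Kh),
M(t) the meal glucose flux and FI(t) the exogenous insulin flux (which
enters the insulin balance additively).  Hepatic glucose production
m0/(I0+I) is suppressed by insulin.  Bistability requires Kg ≫ Kf: the
inactivation response must keep rising where secretion has saturated, so
that total steady-state secretion *decreases* with glucose somewhere.

The adaptation rate `a` is specified in the literature this model builds
on only by its signs (c rises when fasting glucose exceeds the target
G0 = 80 mg/dL and there is headroom, falls below it, saturates at c_max).
We use the linear form a = ka·c_max·(G_f − G0), hard-clipped to keep
c ∈ [0, c_max], with ka = 1e-3 /(mg/dL·day).  Every analysis here operates
in one of the two quasi-static limits (c pinned at c_max in chronic
hyperglycemia, or c reduced so that fasting G = G0), so any sign-correct
form gives the same results; ka only sets an irrelevant transient scale.

## Calibration

Fast-subsystem constants are the published minimal-model values
(γ = 432/day, SE = 1.44/day, SI = 0.72 mL·μU⁻¹·day⁻¹, Kf = √20000
≈ 141.4 mg/dL, reference hepatic production R0 = 864 mg/dL/day); they are
stored as named constants so they can be audited or overridden.  Derived
defaults:

* **m0 = 2·I0·R0** with I0 = 5 μU/mL, so hepatic production equals R0
  when I = I0.  At the calibrated fasting state this gives fasting insulin
  ≈ 7.05 μU/mL and fasting HGP ≈ 17% below R0.
* **Kg** from the single available anchor g(100 mg/dL) = 6e-4, giving
  Kg ≈ 4081.3 mg/dL.
* **Kh = 250 mg/dL.**  No printed value exists; 250 lies between Kf and
  Kg so that irreversible death engages mainly at severe hyperglycemia.
  Note that h(110) ≈ 0.16 is not negligible: for the high-kD phenotype D
  this makes even the calibrated baseline slowly self-destructive, so D's
  basin switch can precede the high-sugar challenge.  This is a property
  of the stated parameter world, not an integration artifact.
* **Secretion capacity Q = c_max·β_TOT** per phenotype, chosen so the
  meal-free fixed point (β at its quasi-steady fraction, c = c_max) sits
  exactly at 110 mg/dL — mild fasting hyperglycemia, i.e. advanced
  prediabetes.  β_TOT is normalised to 1 and Q carried by c_max; only the
  product matters.

Phenotype presets (rates in 1/day): A (kIN=4.8, kRE=0.04, kD=1e-3,
conventional-T2D-like), B (kIN=71, KPD-prone), C (kRE=0.028, slow
reactivation), D (kD=0.07, fast death).  Daily meal budgets are fractions
of the *fasting* HGP (≈ 717 mg/dL/day): 3% in normal periods, 70% during
a high-sugar month.

## Equilibria

Over weeks, irreversible death is negligible and the beta pools
equilibrate to the quasi-steady fraction β/β_TOT = 1/(1+(kIN/kRE)·g(G)).
Substituting into the glucose balance at constant (M, FI) and clearing
Hill denominators yields a degree-≤9 polynomial in G whose non-negative
real roots are the steady-state glucose values.  Numerics:

* roots via the companion matrix (numpy `polyroots`) after rescaling
  G → G/100 — raw coefficients span ~20 orders of magnitude because of
  the mg/dL scale, and unscaled trimming/eigensolves lose roots;
* each root is polished by Newton iteration on the steady-state residual
  (relative residual < 1e-9) and deduplicated within 1e-6 mg/dL;
* physical window G ∈ [0, 2000] mg/dL; scans may probe negative M or FI
  for conceptual completeness.

**Stability.**  The death-free flow conserves β+β_IN, so the 4-state
Jacobian always has a structural zero eigenvalue.  Stability is therefore
judged on the conservation manifold: the 3-state (G, I, β) Jacobian with
β_IN slaved to the point's total, central differences with step
1e-6·(1+|x|), stable iff all eigenvalue real parts are negative.

**Branch labels.**  Within a bistable set, labels follow glucose order
(high_beta < intermediate < low_beta).  A monostable point is labelled by
the sign of d ln s/dG at its G, where s(G) = c·β(G)·f(G) is the
quasi-steady secretion curve: the healthy branch lives on the rising limb,
the collapsed branch on the falling limb.  This is a local criterion
chosen over scan-continuation for determinism and cost; it agrees with
continuation on all tested cases but is in principle ambiguous exactly at
a saddle-node.

**Scans and phase diagram.**  One-parameter sweeps (M, FI, SI, β_TOT,
kIN/kRE) report the full fixed-point set per grid value and refine any
stable-count change by bisection to 1e-4 relative — these are the
saddle-node locations.  The (SI, β_TOT) phase diagram classifies each cell
as monostable high-β / bistable / monostable low-β; when the healthy
branch would sit below G0 = 80 mg/dL, c is reduced (adaptation no longer
saturated) so fasting glucose floors at G0, and such cells are always
monostable high-β.

## Simulation

`scipy.integrate.solve_ivp` with the Radau implicit Runge–Kutta method
(the system is stiff: insulin clears at 432/day against death at
1e-3/day).  Integration is split at every meal-pulse edge and day
boundary so the discontinuous meal flux is constant within each solver
call.  Defaults rtol = 1e-8, atol = 1e-10; scenario outcomes are
tolerance-stable (identical event summaries at 1e-6, which the test suite
uses for speed).  Solver-tolerance-sized overshoots of exact invariants
(positivity, c ≤ c_max) are clipped after each segment.

Meals are rectangular pulses, 3 per day (08:00, 13:00, 19:00), 30 min
each, equal shares of the phase's daily budget; only daily totals are
physiologically constrained, the shape affects only fast transients.

The canonical phenotype scenario: ≥60 d baseline (3% meals), 30 d
high-sugar month (70%), then — if the patient has crossed into the
hyperglycemic basin — titrated insulin, then ≥120 d insulin-free
follow-up.  Titration holds FI piecewise-constant, multiplying it every
3 days by (daily-mean G / target G), clipped to [1/2, 2]; the starting
dose is the clamp estimate γ·I*(target) − current secretion.  Treatment
ends ("well controlled") when the patient is back in the healthy basin
*and* the fasting glucose they would settle at without insulin — solving
the fast subsystem at their current β — is ≤ 130 mg/dL (the ADA control
threshold).  Checking the off-insulin glucose, rather than the insulin-
assisted glucose, is what separates phenotypes B and C: insulin controls
glucose within days for both, but C's slower reactivation delays the
recovery of endogenous control.

Basin membership compares β to the meal-free unstable fixed point's β
(glucose dynamics are fast, so that β is effectively the separatrix);
a state exactly at the threshold is classified hyperglycemic
(conservative), and monostable regimes are flagged and classified healthy.

## Treatment planner

With zero sugar intake and glucose clamped at a target Gmin, the pool
equations are linear:

    β(t)/β_TOT = e^(−λt)·(β0 − β∞) + β∞,   λ = kRE + kIN·g(Gmin),
    β∞ = kRE/λ.

The clamp insulin I* is the positive root of
SI·Gmin·I² + Gmin·(SE+SI·I0)·I + SE·Gmin·I0 − m0 = 0, and the exogenous
flux FI(t) = γ·I* − c·β_TOT·β_frac(t)·f(Gmin) decays exponentially as the
recovering cells take over (clipped at zero and flagged if secretion
overshoots the clamp requirement).  Remission time is the closed-form
crossing of the healthy fixed-point fraction; it is finite exactly when
Gmin is below the healthy fixed-point glucose (110 mg/dL for the
calibrated presets) and grows without bound as Gmin approaches it.  The
default presenting state β0 is the low-β stable fixed point's fraction.
A within-ε remission criterion is exposed as an option (`epsilon`).

## What the synthetic world does and does not establish

All inputs are parameter sets; there is no patient data and no fitting.
The scenarios emulate the *qualitative* clinical course of KPD — rapid
onset after a high-sugar period, insulin-induced remission, slower
remission with slow reactivation, failed remission with fast death.
Green tests establish internal consistency (closed forms vs integration,
companion-matrix roots vs bisection, ODE limits vs analytic fixed points)
and reproduction of the few printed quantitative anchors (fasting insulin
≈ 7 μU/mL, g(100) = 6e-4, ~10%/day inactivation at 150 mg/dL, the 201.6
g/day flux cross-check).  They do not establish anything about real
patients: meal pulses are schematic, insulin pharmacokinetics and action
delay are absent, renal glucose clearance and ketone chemistry are not
modelled, and the glucotoxicity rates were chosen to span phenotypes, not
fitted.

## Known limitations

* Exact treatment durations in the scenario runner depend on the stop
  criterion and titration details; only orderings and outcomes are
  meaningful.
* The monostable branch label is local (secretion-slope sign) and could
  in principle disagree with continuation exactly at a bifurcation point.
* Saddle-node refinement brackets stable-count changes on the scan grid;
  a bistability window narrower than the grid spacing can be missed.
* With the default Kh, phenotype D's baseline is already slowly
  collapsing (see Calibration); users studying kD sensitivity should vary
  Kh alongside it.
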