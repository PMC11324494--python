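# Methods

## Model and assumptions

The package implements a closed-form fluid–structure model of flow through
the ascending aorta. Its physical picture: the heart supplies initial
kinetic energy, the pre-stretched elastic wall stores a strain-energy
density increment (SEDI) between diastole and systole, and wall shear
dissipates energy; balancing these per stroke yields an analytical
expression for the mean flow. Assumptions inherited by every result:

- **Linear elasticity in the physiological range.** The wall is a
  thin-walled, linearly elastic tube between diastolic and systolic
  pressure; no hyperelastic (Fung/Holzapfel) constitutive behaviour.
- **Laminar flow.** The friction loss factor is λ = 64/Re; aortic Re stays
  well below the turbulence threshold except at peak systole, which the
  model does not resolve.
- **No waveform.** Only cycle-integrated quantities (per-stroke and
  per-minute flow) are computed; there is no pulsatile, Windkessel or
  Navier–Stokes component, and no cerebral autoregulation dynamics.
- **CBF as a fraction of systemic perfusion.** Cerebral flow is reported as
  the 12–15% band of mean aortic flow carried by the carotids, not from a
  cerebral circulation model.

## Conventions that needed fixing

The defining expressions leave several groupings and symbols open; the
package fixes them as follows, each centralized in one function so an
alternative reading is a one-line change.

- **Unsubscripted h and D** in the characteristic velocity, the dissipation
  coefficient and the stroke-flow correction are the **diastolic** wall
  thickness and inner lumen diameter. This reproduces the reference
  calculations for both age groups to well under 1% on V, Q and Q̄;
  arithmetic means of systolic/diastolic values miss the stiff 80-y
  baseline by ~3%.
- **Specific weight γ = ρg** with ρ = 1050 kg/m³ and g = 9.81 m/s²
  (overridable); the characteristic velocity V is a flow distance per unit
  weight per stroke, so γ carries the conversion between stored energy
  density and distance.
- **Flow area A_f = πD_d²/4** (diastolic lumen) unless supplied explicitly.
- **Axial pre-stretch λ_z** multiplies V once; it is not re-applied in the
  stroke-flow expression.
- **Units**: mmHg/mm/MPa at the API, SI internally, 1 mmHg = 133.322 Pa
  fixed.
- **Mean pressure** P = (2p_d + p_s)/3.
- **Reynolds number** is an input constant by default (the reference grid
  supplies 909.09 and 833). An optional `re_mode="fixed-point"` iterates
  V → Re = ρVD/μ → λ → β → V to a 1e-8 relative tolerance (≤100
  iterations) for users who prefer self-consistency; it is not used in the
  reference reproduction.
- **Rounding for report output** mirrors the reference display: pressures
  1 decimal, V and Q 3 decimals, Q̄ 2 decimals, CBF floored to whole
  mL/min (the floor convention matches the published CBF row within
  1 mL/min everywhere; round-half does not), percent changes 2 decimals.
  All comparisons and percent changes are computed from unrounded values.

## Calibration of K

The dissipation shape coefficient K enters β quadratically, so published β
values invert in closed form: K = √(β/β(K=1)); multiple targets give a
least-squares fit on relative β errors, minimized at
K² = Σr/Σr² with r_i = β_i(K=1)/β_i. The reference grid holds β constant
within each age group while pulse pressure varies, so the implied K drifts
(0.99 at the 60-y baseline down to 0.66 at the smallest pulse pressure;
group-level least-squares fits are 0.806 / 0.845, within 10% of each
other). The calibration report exposes this drift. Because of it,
reproduction of the reference outputs uses the published β values
directly ("as-printed" mode, the default); "self-consistent" mode
recomputes β from the fitted K (bundled in `data/calibration.yaml`,
K̂ = 0.8273 across all 14 columns).

## Scenario engine

OH scenarios drop systolic/diastolic pressure against an age-specific
baseline; geometry, rheology, stiffness and pre-stretch stay at baseline
values because OH onset is fast relative to vascular remodelling. The
reference parameterization assigns the perturbed (orthostatic) columns a
slightly different constraint coefficient than the resting 60-y baseline
(0.0435 vs 0.038) and a different β in the 80-y group (3.01 vs 2.91); these
are honored as given and applied whenever a nonzero drop is requested, so a
zero drop reproduces the baseline column exactly. Percent changes are
always computed from unrounded mean flows. Cross-group comparisons
(aged hypertensive states vs the young baseline) follow the same rule;
note the corresponding published figures were evidently derived from
rounded two-decimal flows, so our unrounded values sit up to ~0.5 pp away.

## Stenosis modes

Carotid stenosis is expressed through the remaining flow-area ratio
(published degree → ratio map: 50%→0.50, 70%→0.374, 80%→0.312, 90%→0.252)
and reported as a percent change of CBF, since no carotid geometry column
is published.

- **proportional**: ΔCBF% = 100(ratio − 1); flow scales with area.
- **recomputed** (default): lumen diameters scale by √ratio at fixed wall
  thickness, β rescales as 1/D, and the flow is re-solved. This is *more*
  severe than proportional (−55.1% at ratio 0.5 on the 60-y baseline)
  because narrowing the lumen at fixed wall raises the dissipation
  coefficient.

The published ΔCBF values (−41.8 … −61.8%) fall between no closed-form
mode identified here; their derivation is under-specified, so
`stenosis_report` carries both modes *and* the residuals against the
published numbers rather than asserting agreement.

## Synthetic stretch-inflation generator

No measured porcine dataset is published, so the experiment module pairs
the analysis code with a generator emulating the bench protocol: axial
pre-stretch ratios {1.33, 1.23, 1.08, 1.05, 1.01} (the autopsy-derived
human aging trajectory), pressure sweep 60–120 mmHg in 5 mmHg steps
(around the normal porcine 113/60 mmHg), porcine-scale geometry (22 mm
unloaded inner diameter, 1.5 mm wall at unit stretch, both thinning by
1/√λ_z under axially incompressible stretch), and an imposed modulus law
E(λ_z) = 0.30·exp(1.9(1.33 − λ_z)) MPa — 0.30 MPa young to 0.55 MPa aged,
steepest at low pre-stretch, and well below human moduli as porcine vessels
are. The pressure–diameter relation is linear with a 10% pre-distension at
the bottom of the sweep (the nonlinear toe region below 60 mmHg is not
modelled; the unloaded diameter enters only as the strain reference), the
outer diameter follows from conservation of the wall annulus, and the
distension slope is chosen in closed form so that the thin-wall analysis
at 113/60 mmHg returns the imposed modulus exactly. Gaussian noise
(default sd 0.05 mm, laser-rangefinder scale) is added to the
outer-diameter readings only.

What the generator does **not** emulate: constitutive nonlinearity within
the sweep, hysteresis/viscoelasticity, axial force feedback, wall
inhomogeneity, and correlated measurement error. Passing recovery tests on
this family therefore demonstrates that the analysis inverts a linear
thin-wall vessel correctly and is robust to independent diameter noise —
not that it would recover the modulus of a real, nonlinear vessel
unbiasedly. All published bench results (compliance/modulus curves, the
strain-energy drop with aging) are treated as qualitative monotone-trend
targets on this synthetic family, never as numeric targets.

## Analysis numerical choices

- Inner diameter is reconstructed as outer − 2·thickness (only outer
  diameter and thickness are measured).
- The pressure–inner-diameter relation is estimated by ordinary least
  squares across all samples of a sweep (exact for noiseless linear
  records, denoising for measured ones); thickness is linearly
  interpolated between samples. Requested pressures must lie inside the
  sampled range; a (near-)constant diameter sweep raises a validation
  error instead of returning an unbounded modulus.
- SEDI surfaces are evaluated on a (p_s, p_d) grid with cells p_s ≤ p_d
  masked; the reported maximum and argmax come from the unmasked region.
- The degenerate-input policy throughout is fail-loudly: inverted
  pressures, non-positive moduli, walls that swallow the lumen, empty
  calibration target lists and out-of-range grids all raise typed errors.

## Problem sizes

The reference reproduction covers all 14 published columns; the
calibration round-trip property is exercised with 50 random K* draws; the
noise-robustness check runs 100 replicate seeds × 5 pre-stretch levels.
Everything is closed form, so the full suite runs in seconds.

## Known limitations

- The ε_Ap (cross-section area strain) input is stored but enters no
  equation; its intended role is unclear in the source material.
- The implied K is not constant across pulse pressures (see Calibration);
  "as-printed" mode sidesteps this but limits extrapolation beyond the
  bundled columns in "self-consistent" mode.
- The stenosis modes bracket plausible physics but neither reproduces the
  published ΔCBF values; treat those outputs as model-relative, with the
  residual columns as the honest summary.
- Scenario percent changes inherit the published per-column constraint
  coefficients; comparisons across different φ values mix a physical drop
  with a parameterization change (the systolic-dominance property is
  therefore tested at fixed φ).
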