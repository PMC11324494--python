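"""Closed-form hemodynamic model of the ascending aorta.

The model treats the pre-stretched elastic aortic wall as an energy store:
the strain-energy density increment built up between diastole and systole
drives the stroke flow, attenuated by a coupled energy-dissipation
coefficient that bundles wall stiffness, laminar friction and pulse
pressure. All equations are closed-form; no waveform or Navier-Stokes
solving is involved.

Unit policy: arguments are in clinical units (mmHg, mm, MPa); every function
converts to SI internally and converts the result back to its stated unit.

The unsubscripted wall thickness h and lumen diameter D appearing in the
characteristic-velocity, dissipation-coefficient and stroke-flow expressions
are taken at *diastole* (hd, Dd). This convention reproduces the published
reference calculations to well under 1%; it is centralized in
:func:`_wall_thickness_ref` / :func:`_lumen_diameter_ref` so an alternative
reading is a one-line change.
"""
from __future__ import annotations

import math
from typing import Optional, Tuple

from .errors import ValidationError
from .params import ArterialGeometry, BloodRheology, FlowSolution, PressureState, WallMechanics
from .units import (
    m3_per_pa_to_ml_per_mmhg,
    m3_to_l,
    mm2_to_m2,
    mm_to_m,
    mmhg_to_pa,
    mpa_to_pa,
    pa_to_mpa,
)

#: cerebral fraction of systemic perfusion delivered through the carotids
CBF_FRACTIONS: Tuple[float, float] = (0.12, 0.15)


def _wall_thickness_ref(geom: ArterialGeometry) -> float:
    """Reference wall thickness h (m) used where the model writes an unsubscripted h."""
    return mm_to_m(geom.hd)


def _lumen_diameter_ref(geom: ArterialGeometry) -> float:
    """Reference lumen diameter D (m) used where the model writes an unsubscripted D."""
    return mm_to_m(geom.Dd)


def _driver_pa(pstate: PressureState, geom: ArterialGeometry) -> float:
    """Net circumferential load increment alpha_s*ps - alpha_d*pd, Pa."""
    return mmhg_to_pa(geom.alpha_s * pstate.ps - geom.alpha_d * pstate.pd)


def mean_pressure(ps: float, pd: float) -> float:
    """Mean arterial pressure (2*pd + ps)/3, mmHg."""
    if not (ps > pd > 0):
        raise ValidationError(f"require ps > pd > 0, got ps={ps}, pd={pd} mmHg")
    return (2.0 * pd + ps) / 3.0


def friction_factor(Re: float) -> float:
    """Laminar friction loss factor 64/Re (dimensionless)."""
    if Re <= 0:
        raise ValidationError(f"Reynolds number must be positive, got {Re}")
    return 64.0 / Re


def sedi(pstate: PressureState, geom: ArterialGeometry, mech: WallMechanics) -> float:
    """Strain-energy density increment of the wall between diastole and systole.

    du = phi^2 (alpha_s ps - alpha_d pd)^2 / (8 E), in J/m^3. Non-negative;
    zero exactly when the systolic and diastolic circumferential loads
    balance. Scales with phi^2 and inversely with stiffness.
    """
    driver = _driver_pa(pstate, geom)
    return mech.phi**2 * driver**2 / (8.0 * mpa_to_pa(mech.E))


def kinetic_increment(
    pstate: PressureState,
    geom: ArterialGeometry,
    mech: WallMechanics,
    rheo: BloodRheology,
    V: float,
    volume: float = 1.0,
) -> float:
    """Blood kinetic energy increment phi*gamma*(alpha_s ps - alpha_d pd)*V^2/E.

    Integrated over ``volume`` (m^3). Zero at V = 0; quadratic in V.
    """
    if V < 0:
        raise ValidationError(f"characteristic velocity must be non-negative, got {V}")
    driver = _driver_pa(pstate, geom)
    return mech.phi * rheo.gamma * driver * V**2 / mpa_to_pa(mech.E) * volume


def dissipation_increment(
    geom: ArterialGeometry,
    mech: WallMechanics,
    rheo: BloodRheology,
    V: float,
    area: float = 1.0,
) -> float:
    """Energy dissipated by wall shear: -phi*gamma*lambda*(Ds - Dd)*K^2*V^2.

    Integrated over wall ``area`` (m^2). Non-positive; zero only at V = 0.
    Requires the shape coefficient K on ``mech``.
    """
    if V < 0:
        raise ValidationError(f"characteristic velocity must be non-negative, got {V}")
    if mech.K is None:
        raise ValidationError("dissipation increment requires the shape coefficient K")
    lam = rheo.lam_f
    dD = mm_to_m(geom.Ds - geom.Dd)
    return -mech.phi * rheo.gamma * lam * dD * mech.K**2 * V**2 * area


def beta_coefficient(
    pstate: PressureState,
    geom: ArterialGeometry,
    mech: WallMechanics,
    rheo: BloodRheology,
    K: Optional[float] = None,
) -> float:
    """Coupled energy-dissipation coefficient.

    beta = 4 E lambda K^2 (hd - hs) / (D (ps - pd) phi), dimensionless.
    Grows with stiffness and friction, shrinks with pulse pressure.
    """
    K = mech.K if K is None else K
    if K is None:
        raise ValidationError("beta requires the shape coefficient K")
    if not geom.hd > geom.hs:
        raise ValidationError(
            f"beta undefined: need hd > hs, got hd={geom.hd}, hs={geom.hs} mm"
        )
    lam = rheo.lam_f
    num = 4.0 * mpa_to_pa(mech.E) * lam * K**2 * mm_to_m(geom.hd - geom.hs)
    den = _lumen_diameter_ref(geom) * mmhg_to_pa(pstate.pp) * mech.phi
    return num / den


def characteristic_velocity(
    pstate: PressureState,
    geom: ArterialGeometry,
    mech: WallMechanics,
    rheo: BloodRheology,
    beta: Optional[float] = None,
) -> float:
    """Characteristic velocity V (m): flow distance per unit weight per stroke.

    V = lam_z * sqrt( phi h (alpha_s ps - alpha_d pd) / (D gamma (1 + beta)) ).
    Proportional to the axial pre-stretch; attenuated by 1 + beta.
    """
    if beta is None:
        beta = mech.beta
    if beta is None:
        beta = beta_coefficient(pstate, geom, mech, rheo)
    if beta <= -1.0:
        raise ValidationError(f"beta must exceed -1, got {beta}")
    driver = _driver_pa(pstate, geom)
    if driver <= 0:
        raise ValidationError(
            "no net driving energy: alpha_s*ps must exceed alpha_d*pd "
            f"(got {geom.alpha_s * pstate.ps:.1f} vs {geom.alpha_d * pstate.pd:.1f} mmHg)"
        )
    h = _wall_thickness_ref(geom)
    D = _lumen_diameter_ref(geom)
    return geom.lam_z * math.sqrt(mech.phi * h * driver / (D * rheo.gamma * (1.0 + beta)))


def stroke_flow(
    pstate: PressureState,
    geom: ArterialGeometry,
    mech: WallMechanics,
    V: float,
) -> float:
    """Per-stroke flow Q (L/beat).

    Q = (1 + phi D P / (E h)) * Af * V. The leading factor is a small
    distensibility correction (a few percent for physiological stiffness);
    the axial pre-stretch factor is already contained in V and is not
    applied again.
    """
    if V < 0:
        raise ValidationError(f"characteristic velocity must be non-negative, got {V}")
    h = _wall_thickness_ref(geom)
    D = _lumen_diameter_ref(geom)
    Eh = mpa_to_pa(mech.E) * h
    if Eh == 0:
        raise ValidationError("E*h must be nonzero")
    corr = 1.0 + mech.phi * D * mmhg_to_pa(pstate.pmean) / Eh
    return m3_to_l(corr * mm2_to_m2(geom.flow_area) * V)


def mean_flow(Q: float, n: float) -> float:
    """Mean flow per minute Qbar = n*Q (L/min) from the unrounded stroke flow."""
    if Q <= 0:
        raise ValidationError(f"stroke flow must be positive, got {Q}")
    if n <= 0:
        raise ValidationError(f"pulse rate must be positive, got {n}")
    return n * Q


def cbf_range(
    Qbar: float,
    fractions: Tuple[float, float] = CBF_FRACTIONS,
    rounded: bool = False,
) -> Tuple[float, float]:
    """Cerebral blood flow bounds (mL/min): 12-15% of systemic perfusion.

    With ``rounded=True`` the bounds are floored to whole mL/min, the
    display convention of the reference tabulation.
    """
    if Qbar < 0:
        raise ValidationError(f"mean flow must be non-negative, got {Qbar}")
    lo, hi = (fractions[0] * Qbar * 1000.0, fractions[1] * Qbar * 1000.0)
    if not lo <= hi:
        raise ValidationError(f"CBF fractions must be ordered, got {fractions}")
    if rounded:
        return (math.floor(lo), math.floor(hi))
    return (lo, hi)


def compliance(geom: ArterialGeometry, pstate: PressureState, l: float = 1.0) -> float:
    """Aortic compliance per segment length l (m): C = pi l (Ds^2 - Dd^2)/(4 PP).

    Returned in mL/mmHg. Vanishes in the rigid-tube limit Ds -> Dd and is
    inversely proportional to pulse pressure.
    """
    dsq = mm_to_m(geom.Ds) ** 2 - mm_to_m(geom.Dd) ** 2
    if dsq <= 0:
        raise ValidationError("compliance requires Ds > Dd")
    c_si = math.pi * l * dsq / (4.0 * mmhg_to_pa(pstate.pp))
    return m3_per_pa_to_ml_per_mmhg(c_si)


def circ_modulus(geom: ArterialGeometry, pstate: PressureState) -> float:
    """Circumferential elastic modulus E = D P Do / (2 h (Ds - Dd)), MPa.

    Thin-wall estimate from the systolic-diastolic distension; requires the
    reference inner diameter Do on the geometry.
    """
    if geom.Do is None:
        raise ValidationError("circumferential modulus requires the reference diameter Do")
    dD = geom.Ds - geom.Dd
    if dD <= 0:
        raise ValidationError("circumferential modulus undefined for Ds <= Dd")
    # length units cancel in D*Do/(h*dD); P carries the pascals
    e_pa = geom.Dd * mmhg_to_pa(pstate.pmean) * geom.Do / (2.0 * geom.hd * dD)
    return pa_to_mpa(e_pa)


def circ_stress(geom: ArterialGeometry, pstate: PressureState, phi: float) -> float:
    """Circumferential wall stress sigma_theta = phi D P / (2 h), Pa."""
    return phi * geom.Dd * mmhg_to_pa(pstate.pmean) / (2.0 * geom.hd)


def circ_strain(geom: ArterialGeometry) -> float:
    """Circumferential strain increment (Ds - Dd)/Do between diastole and systole."""
    if geom.Do is None:
        raise ValidationError("circumferential strain requires the reference diameter Do")
    return (geom.Ds - geom.Dd) / geom.Do


def solve_flow(
    pstate: PressureState,
    geom: ArterialGeometry,
    mech: WallMechanics,
    rheo: BloodRheology,
    n: float,
    beta: Optional[float] = None,
    cbf_fractions: Tuple[float, float] = CBF_FRACTIONS,
    re_mode: str = "fixed",
    re_tol: float = 1e-8,
    re_maxiter: int = 100,
) -> FlowSolution:
    """Run the full pipeline: beta -> V -> Q -> Qbar -> CBF (+ energy terms).

    ``beta`` as given takes precedence ("as-printed" mode); otherwise it is
    recomputed from ``mech.K`` ("self-consistent" mode). With
    ``re_mode="fixed-point"`` the Reynolds number is iterated to
    self-consistency (Re = rho V D / mu) instead of being taken as a given
    input; this requires K, since the friction factor feeds back into beta.
    """
    if re_mode not in ("fixed", "fixed-point"):
        raise ValidationError(f"unknown Re mode {re_mode!r}")
    if beta is None:
        beta = mech.beta

    if re_mode == "fixed-point":
        if mech.K is None:
            raise ValidationError("fixed-point Re mode requires the shape coefficient K")
        D = _lumen_diameter_ref(geom)
        re = rheo.Re if rheo.Re is not None else 1000.0
        V = None
        for _ in range(re_maxiter):
            rheo_i = BloodRheology(mu=rheo.mu, rho=rheo.rho, g=rheo.g, Re=re)
            beta_i = beta_coefficient(pstate, geom, mech, rheo_i)
            V_new = characteristic_velocity(pstate, geom, mech, rheo_i, beta=beta_i)
            re_new = rheo.rho * V_new * D / rheo.mu
            if V is not None and abs(V_new - V) <= re_tol * abs(V_new):
                re = re_new
                V = V_new
                break
            re, V = re_new, V_new
        rheo = BloodRheology(mu=rheo.mu, rho=rheo.rho, g=rheo.g, Re=re)
        beta = beta_coefficient(pstate, geom, mech, rheo)

    V = characteristic_velocity(pstate, geom, mech, rheo, beta=beta)
    Q = stroke_flow(pstate, geom, mech, V)
    Qbar = mean_flow(Q, n)
    lo, hi = cbf_range(Qbar, cbf_fractions)
    du = sedi(pstate, geom, mech)
    dK = kinetic_increment(pstate, geom, mech, rheo, V)
    dw = dissipation_increment(geom, mech, rheo, V) if mech.K is not None else None
    return FlowSolution(
        V=V, Q=Q, n=n, Qbar=Qbar, cbf_lo=lo, cbf_hi=hi, beta=beta, du=du, dK=dK, dw_tau=dw
    )
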