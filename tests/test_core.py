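"""Unit tests for the closed-form hemodynamic model equations."""
import dataclasses
import math

import numpy as np
import pytest

import aortaflow as af
from aortaflow.core import (
    beta_coefficient,
    cbf_range,
    characteristic_velocity,
    circ_modulus,
    circ_strain,
    circ_stress,
    compliance,
    dissipation_increment,
    friction_factor,
    kinetic_increment,
    mean_flow,
    mean_pressure,
    sedi,
    solve_flow,
    stroke_flow,
)
from aortaflow.errors import ValidationError
from aortaflow.params import ArterialGeometry, BloodRheology, PressureState, WallMechanics

#: implied shape coefficient of the 60-y baseline (closed-form inversion of beta = 1.24)
K60 = 0.9933247806107262


@pytest.mark.parametrize(
    "ps,pd,expected",
    [(129.1, 79.8, 96.2), (154.0, 76.0, 102.0), (120.0, 80.0, 280.0 / 3.0)],
)
def test_mean_pressure(ps, pd, expected):
    assert mean_pressure(ps, pd) == pytest.approx(expected, abs=0.05)


@pytest.mark.parametrize("ps,pd", [(90.0, 90.0), (80.0, 90.0), (-10.0, -20.0), (90.0, 0.0)])
def test_mean_pressure_rejects_degenerate(ps, pd):
    with pytest.raises(ValidationError):
        mean_pressure(ps, pd)


@pytest.mark.parametrize(
    "re,expected", [(909.09, 0.0704), (64.0, 1.0), (833.0, 0.0768)]
)
def test_friction_factor(re, expected):
    assert friction_factor(re) == pytest.approx(expected, rel=1e-3)


def test_friction_factor_rejects_nonpositive_re():
    with pytest.raises(ValidationError):
        friction_factor(0.0)


class TestSedi:
    def test_baseline_value(self, base60):
        # phi^2 (a_s ps - a_d pd)^2 / (8 E) at the 60-y baseline ~= 7.35 J/m^3
        du = sedi(base60.pstate, base60.geom, base60.mech)
        assert du == pytest.approx(7.35, rel=0.01)
        assert du == pytest.approx(7.37640927561367, rel=1e-9)  # regression

    def test_square_of_net_load_increment(self):
        # du matches the closed form phi^2 driver^2 / 8E and therefore
        # vanishes quadratically on the locus alpha_s ps = alpha_d pd
        geom = ArterialGeometry(Ds=30.0, Dd=29.0, hs=1.4, hd=1.5)
        mech = WallMechanics(E=0.7, phi=0.04)
        pstate = PressureState(ps=110.0, pd=100.0)
        driver_pa = (geom.alpha_s * pstate.ps - geom.alpha_d * pstate.pd) * 133.322
        expected = mech.phi**2 * driver_pa**2 / (8 * mech.E * 1e6)
        assert sedi(pstate, geom, mech) == pytest.approx(expected, rel=1e-12)
        assert sedi(pstate, geom, mech) >= 0.0

    def test_quadratic_in_phi(self, base60):
        mech2 = dataclasses.replace(base60.mech, phi=2 * base60.mech.phi)
        assert sedi(base60.pstate, base60.geom, mech2) == pytest.approx(
            4 * sedi(base60.pstate, base60.geom, base60.mech)
        )

    def test_rejects_nonpositive_modulus(self, base60):
        with pytest.raises(ValidationError):
            WallMechanics(E=0.0, phi=0.04)


class TestEnergyIncrements:
    def test_kinetic_zero_at_rest_and_quadratic(self, base60):
        args = (base60.pstate, base60.geom, base60.mech, base60.rheo)
        assert kinetic_increment(*args, V=0.0) == 0.0
        k1 = kinetic_increment(*args, V=0.1)
        assert kinetic_increment(*args, V=0.2) == pytest.approx(4 * k1)
        assert kinetic_increment(*args, V=0.123) == pytest.approx(
            1.4308266002910583, rel=1e-9
        )  # regression

    def test_kinetic_rejects_negative_velocity(self, base60):
        with pytest.raises(ValidationError):
            kinetic_increment(base60.pstate, base60.geom, base60.mech, base60.rheo, V=-0.1)

    def test_dissipation_sign_and_scaling(self, base60):
        mech = dataclasses.replace(base60.mech, K=K60)
        assert dissipation_increment(base60.geom, mech, base60.rheo, V=0.0) == 0.0
        d1 = dissipation_increment(base60.geom, mech, base60.rheo, V=0.123)
        assert d1 < 0
        assert d1 == pytest.approx(-0.0004936157465839443, rel=1e-9)  # regression
        # halving Re doubles the friction factor, hence |dw|
        rheo2 = BloodRheology(Re=base60.rheo.Re / 2)
        assert dissipation_increment(base60.geom, mech, rheo2, V=0.123) == pytest.approx(2 * d1)


class TestBeta:
    def test_reproduces_printed_beta_with_implied_K(self, base60):
        mech = dataclasses.replace(base60.mech, K=K60)
        assert beta_coefficient(base60.pstate, base60.geom, mech, base60.rheo) == pytest.approx(
            1.24, rel=1e-12
        )

    def test_zero_K_gives_zero(self, base60):
        assert beta_coefficient(base60.pstate, base60.geom, base60.mech, base60.rheo, K=0.0) == 0.0

    def test_requires_wall_thickening(self, base60):
        geom = dataclasses.replace(base60.geom, hd=base60.geom.hs)
        with pytest.raises(ValidationError):
            beta_coefficient(base60.pstate, geom, base60.mech, base60.rheo, K=1.0)


class TestCharacteristicVelocity:
    def test_printed_values(self, base60, base80):
        v60 = characteristic_velocity(base60.pstate, base60.geom, base60.mech, base60.rheo)
        assert v60 == pytest.approx(0.123, rel=0.03)
        assert v60 == pytest.approx(0.12291091592507726, rel=1e-9)  # regression
        v80 = characteristic_velocity(base80.pstate, base80.geom, base80.mech, base80.rheo)
        assert v80 == pytest.approx(0.119, rel=0.03)

    def test_linear_in_prestretch(self, base60):
        geom2 = dataclasses.replace(base60.geom, lam_z=2 * base60.geom.lam_z)
        v1 = characteristic_velocity(base60.pstate, base60.geom, base60.mech, base60.rheo)
        v2 = characteristic_velocity(base60.pstate, geom2, base60.mech, base60.rheo)
        assert v2 == pytest.approx(2 * v1)

    def test_rejects_unphysical_beta(self, base60):
        with pytest.raises(ValidationError):
            characteristic_velocity(
                base60.pstate, base60.geom, base60.mech, base60.rheo, beta=-1.5
            )


class TestFlow:
    def test_stroke_flow_printed(self, base60):
        q = stroke_flow(base60.pstate, base60.geom, base60.mech, V=0.12291091592507726)
        assert q == pytest.approx(0.096, rel=0.03)
        assert q == pytest.approx(0.0966043740389042, rel=1e-9)  # regression

    def test_distensibility_correction_is_small(self, base60):
        V = 0.123
        q = stroke_flow(base60.pstate, base60.geom, base60.mech, V)
        ratio = q / (base60.geom.flow_area * 1e-6 * V * 1e3)
        assert 1.0 < ratio < 1.1

    def test_zero_velocity_gives_zero_flow(self, base60):
        assert stroke_flow(base60.pstate, base60.geom, base60.mech, 0.0) == 0.0

    def test_mean_flow(self):
        assert mean_flow(0.09, 67.0) == pytest.approx(6.03)
        with pytest.raises(ValidationError):
            mean_flow(0.09, 0.0)

    def test_full_pipeline_baseline(self, base60):
        sol = solve_flow(base60.pstate, base60.geom, base60.mech, base60.rheo, base60.n)
        assert sol.Qbar == pytest.approx(6.37, rel=0.01)
        assert sol.du > 0

    def test_fixed_point_re_mode_converges(self, base60):
        mech = dataclasses.replace(base60.mech, K=K60, beta=None)
        sol = solve_flow(
            base60.pstate, base60.geom, mech, base60.rheo, base60.n, re_mode="fixed-point"
        )
        # at convergence the Reynolds number is consistent with V
        re = base60.rheo.rho * sol.V * base60.geom.Dd * 1e-3 / base60.rheo.mu
        rheo = BloodRheology(Re=re)
        beta = beta_coefficient(base60.pstate, base60.geom, mech, rheo)
        v = characteristic_velocity(base60.pstate, base60.geom, mech, rheo, beta=beta)
        assert v == pytest.approx(sol.V, rel=1e-7)


class TestCbfRange:
    def test_printed_bounds_within_one_ml(self):
        lo, hi = cbf_range(6.37, rounded=True)
        assert abs(lo - 765) <= 1 and abs(hi - 956) <= 1
        lo, hi = cbf_range(4.58, rounded=True)
        assert abs(lo - 550) <= 1 and abs(hi - 688) <= 1

    def test_zero_flow(self):
        assert cbf_range(0.0) == (0.0, 0.0)

    def test_bounds_ordered(self):
        lo, hi = cbf_range(5.0)
        assert lo < hi


class TestWallProperties:
    def test_compliance_baseline_regression(self, base60):
        c = compliance(base60.geom, base60.pstate, l=1.0)
        assert c == pytest.approx(1.223500587199269, rel=1e-9)

    def test_compliance_halves_when_pp_doubles(self, base60):
        p2 = PressureState(ps=base60.pstate.pd + 2 * base60.pstate.pp, pd=base60.pstate.pd)
        assert compliance(base60.geom, p2) == pytest.approx(
            compliance(base60.geom, base60.pstate) / 2
        )

    def test_compliance_rigid_limit(self, base60):
        geom = dataclasses.replace(base60.geom, Ds=base60.geom.Dd + 1e-9)
        assert compliance(geom, base60.pstate) == pytest.approx(0.0, abs=1e-6)

    def test_circ_modulus_porcine_like_regression(self):
        geom = ArterialGeometry(Ds=24.25, Dd=23.75, hs=2.0, hd=2.0, Do=23.0)
        pstate = PressureState(ps=120.0, pd=75.0)  # pmean = 90 mmHg
        # Dd*P*Do/(2*hd*(Ds-Dd)) with Dd = 23.75 here
        expected = 23.75 * 90 * 133.322 * 23.0 / (2 * 2.0 * 0.5) / 1e6
        assert circ_modulus(geom, pstate) == pytest.approx(expected, rel=1e-12)

    def test_circ_modulus_doubles_when_distension_halves(self, base60):
        geom1 = dataclasses.replace(base60.geom, Do=30.0)
        dd = geom1.Dd
        geom2 = dataclasses.replace(geom1, Ds=dd + (geom1.Ds - dd) / 2)
        assert circ_modulus(geom2, base60.pstate) == pytest.approx(
            2 * circ_modulus(geom1, base60.pstate)
        )

    def test_stress_strain_modulus_consistency(self):
        """E * eps_theta == sigma_theta/phi * (Do/(...)) under the thin-wall formulas."""
        geom = ArterialGeometry(Ds=24.0, Dd=23.0, hs=1.9, hd=2.0, Do=22.0)
        pstate = PressureState(ps=113.0, pd=60.0)
        phi = 0.04
        e_pa = circ_modulus(geom, pstate) * 1e6
        assert e_pa * circ_strain(geom) == pytest.approx(circ_stress(geom, pstate, phi) / phi)


def test_qbar_monotone_in_pressures(inputs):
    """Mean flow rises with systolic and falls with diastolic pressure."""
    for label in ("base60", "base80"):
        col = af.column_params(inputs, label)
        for dp in np.arange(-30.0, 31.0, 10.0):
            if dp == 0:
                continue
            # systolic sweep
            qb = []
            for ps in (col.pstate.ps, col.pstate.ps + dp):
                if ps <= col.pstate.pd:
                    continue
                st = PressureState(ps=ps, pd=col.pstate.pd)
                qb.append(solve_flow(st, col.geom, col.mech, col.rheo, col.n).Qbar)
            if len(qb) == 2:
                assert (qb[1] > qb[0]) == (dp > 0)
            # diastolic sweep
            qb = []
            for pd in (col.pstate.pd, col.pstate.pd + dp):
                if pd <= 0 or pd >= col.pstate.ps:
                    continue
                st = PressureState(ps=col.pstate.ps, pd=pd)
                qb.append(solve_flow(st, col.geom, col.mech, col.rheo, col.n).Qbar)
            if len(qb) == 2:
                assert (qb[1] < qb[0]) == (dp > 0)


def test_energy_sanity(base60):
    """du > 0 and dw_tau < 0 whenever there is motion and a net driver."""
    mech = dataclasses.replace(base60.mech, K=K60)
    sol = solve_flow(base60.pstate, base60.geom, mech, base60.rheo, base60.n)
    assert sol.du > 0
    assert sol.dw_tau < 0
    assert sol.dK > 0
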