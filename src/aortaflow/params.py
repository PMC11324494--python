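"""Domain types: pressure state, arterial geometry, blood rheology, wall mechanics.

These are thin validated containers; the model equations live in
:mod:`aortaflow.core`. Fields carry the units a clinician records (mmHg, mm,
MPa); conversion to SI happens inside the equation functions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .errors import ValidationError
from .units import G_STANDARD, RHO_BLOOD


@dataclass(frozen=True)
class PressureState:
    """Systolic/diastolic arterial pressure, mmHg."""

    ps: float
    pd: float

    def __post_init__(self) -> None:
        if not (self.ps > self.pd > 0):
            raise ValidationError(
                f"require ps > pd > 0, got ps={self.ps}, pd={self.pd} mmHg"
            )

    @property
    def pp(self) -> float:
        """Pulse pressure ps - pd, mmHg."""
        return self.ps - self.pd

    @property
    def pmean(self) -> float:
        """Mean pressure (2*pd + ps)/3, mmHg."""
        return (2.0 * self.pd + self.ps) / 3.0


@dataclass(frozen=True)
class ArterialGeometry:
    """Aortic cross-section geometry at systole and diastole.

    Parameters
    ----------
    Ds, Dd
        Systolic/diastolic inner diameter, mm.
    hs, hd
        Systolic/diastolic wall thickness, mm. The wall is thinnest at
        systole (stretched), so ``hd >= hs``.
    Dso, Ddo
        Optional outer diameters, mm.
    Do
        Optional reference (unloaded) inner diameter, mm; needed for the
        circumferential modulus.
    lam_z
        Axial pre-stretch ratio (in-situ length / excised length); declines
        with age from ~1.33 (20 y) to ~1.01 (80 y).
    eps_Ap
        Cross-section area strain. Stored for completeness; it enters no
        equation of the flow model.
    Af
        Optional explicit initial flow area, mm^2. Defaults to the diastolic
        lumen area pi*Dd^2/4.
    """

    Ds: float
    Dd: float
    hs: float
    hd: float
    Dso: Optional[float] = None
    Ddo: Optional[float] = None
    Do: Optional[float] = None
    lam_z: float = 1.0
    eps_Ap: Optional[float] = None
    Af: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.Ds > self.Dd > 0):
            raise ValidationError(
                f"require Ds > Dd > 0, got Ds={self.Ds}, Dd={self.Dd} mm"
            )
        if not (self.hd >= self.hs > 0):
            raise ValidationError(
                f"require hd >= hs > 0, got hs={self.hs}, hd={self.hd} mm"
            )
        if self.Dso is not None and self.Dso <= self.Ds:
            raise ValidationError("outer diameter Dso must exceed inner Ds")
        if self.lam_z < 1.0:
            raise ValidationError(f"axial pre-stretch lam_z must be >= 1, got {self.lam_z}")
        if self.Af is not None and self.Af <= 0:
            raise ValidationError("flow area Af must be positive")

    @property
    def alpha_s(self) -> float:
        """Systolic diameter-to-thickness ratio Ds/hs."""
        return self.Ds / self.hs

    @property
    def alpha_d(self) -> float:
        """Diastolic diameter-to-thickness ratio Dd/hd."""
        return self.Dd / self.hd

    @property
    def flow_area(self) -> float:
        """Initial flow area, mm^2 (diastolic lumen unless given explicitly)."""
        if self.Af is not None:
            return self.Af
        return math.pi * self.Dd**2 / 4.0


@dataclass(frozen=True)
class BloodRheology:
    """Blood material constants and flow regime.

    ``gamma`` (specific weight, N/m^3) is rho*g; the friction loss factor of
    laminar flow is 64/Re. Re is accepted as a given constant by default; see
    :func:`aortaflow.core.solve_flow` for the optional self-consistent mode.
    """

    mu: float = 0.0035  # Pa s
    rho: float = RHO_BLOOD  # kg/m^3
    g: float = G_STANDARD  # m/s^2
    Re: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0 or self.g <= 0:
            raise ValidationError("mu, rho, g must be positive")
        if self.Re is not None and self.Re <= 0:
            raise ValidationError(f"Reynolds number must be positive, got {self.Re}")

    @property
    def gamma(self) -> float:
        """Specific weight of blood, N/m^3."""
        return self.rho * self.g

    @property
    def lam_f(self) -> float:
        """Laminar friction loss factor 64/Re."""
        from .core import friction_factor

        if self.Re is None:
            raise ValidationError("Re is not set; cannot evaluate friction factor")
        return friction_factor(self.Re)


@dataclass(frozen=True)
class WallMechanics:
    """Wall stiffness and coupling coefficients.

    E: circumferential elastic modulus, MPa. phi: perivascular constraint
    coefficient (dimensionless, ~0.04 for the human aorta). K: the
    energy-dissipation shape coefficient (dimensionless, obtained by
    calibration). beta: the coupled energy-dissipation coefficient; when set,
    it is used as given ("as-printed" mode), otherwise it is recomputed from K.
    """

    E: float
    phi: float
    K: Optional[float] = None
    beta: Optional[float] = None

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValidationError(f"elastic modulus E must be positive, got {self.E}")
        if self.phi <= 0:
            raise ValidationError(f"constraint coefficient phi must be positive, got {self.phi}")


@dataclass(frozen=True)
class FlowSolution:
    """Output of the flow pipeline.

    V: characteristic velocity (m, flow distance per unit weight per stroke);
    Q: per-stroke flow (L/beat); n: pulse rate (beats/min); Qbar: mean flow
    (L/min); cbf_lo/cbf_hi: cerebral blood flow bounds (mL/min, unrounded);
    beta: the dissipation coefficient actually used; du: strain-energy density
    increment (J/m^3); dK, dw_tau: kinetic/dissipated energy increments.
    """

    V: float
    Q: float
    n: float
    Qbar: float
    cbf_lo: float
    cbf_hi: float
    beta: float
    du: Optional[float] = None
    dK: Optional[float] = None
    dw_tau: Optional[float] = None
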