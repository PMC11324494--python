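"""Stretch-inflation experiment analysis and synthetic data generation.

A stretch-inflation test pressurizes an excised arterial segment held at a
fixed axial pre-stretch ratio lam_z while recording outer diameter and wall
thickness over a pressure sweep (60-120 mmHg here, the porcine physiological
window around a normal pig pressure of 113/60 mmHg). Loss of axial
pre-stretch is a hallmark of arterial aging, so sweeping lam_z from 1.33
down to 1.01 emulates the aging trajectory of a human thoracic aorta.

No measured porcine dataset is published, so this module pairs the analysis
with a synthetic generator that emulates the protocol: a linear-elastic
thin-walled tube whose circumferential modulus rises as lam_z falls, an
axially incompressible wall (geometry scales with 1/sqrt(lam_z)), and
Gaussian measurement noise on the outer-diameter readings only. Analysis
results on this family are therefore qualitative trend checks with respect
to real vessels, and exact recovery checks with respect to the generator.
"""
from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import sedi
from .errors import ExtrapolationError, ValidationError
from .params import ArterialGeometry, PressureState, WallMechanics
from .units import mmhg_to_pa, mpa_to_pa


@dataclass(frozen=True)
class InflationRecord:
    """One pressure sweep at a fixed axial pre-stretch.

    pressures (mmHg) must be strictly increasing; outer diameters and wall
    thicknesses (mm) are parallel arrays; Do is the reference (unloaded)
    inner diameter used for strain. Monotone diameter/thickness trends hold
    for noiseless data and can be checked with :meth:`check_monotone`.
    """

    lam_z: float
    pressures: np.ndarray
    outer_d: np.ndarray
    thickness: np.ndarray
    Do: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pressures, dtype=float)
        d = np.asarray(self.outer_d, dtype=float)
        h = np.asarray(self.thickness, dtype=float)
        if not (p.shape == d.shape == h.shape) or p.ndim != 1 or p.size < 2:
            raise ValidationError("pressures, outer_d, thickness must be parallel 1-d arrays")
        if np.any(np.diff(p) <= 0):
            raise ValidationError("pressures must be strictly increasing")
        if np.any(d <= 0) or np.any(h <= 0) or self.Do <= 0:
            raise ValidationError("diameters and thicknesses must be positive")
        if np.any(d - 2 * h <= 0):
            raise ValidationError("inner diameter (outer - 2*thickness) must stay positive")
        object.__setattr__(self, "pressures", p)
        object.__setattr__(self, "outer_d", d)
        object.__setattr__(self, "thickness", h)

    @property
    def inner_d(self) -> np.ndarray:
        """Inner diameter reconstructed as outer - 2*thickness, mm."""
        return self.outer_d - 2.0 * self.thickness

    def check_monotone(self) -> None:
        """Assert the noiseless invariants: diameter up, thickness down with pressure."""
        if np.any(np.diff(self.outer_d) < 0):
            raise ValidationError("outer diameter must be non-decreasing with pressure")
        if np.any(np.diff(self.thickness) > 0):
            raise ValidationError("wall thickness must be non-increasing with pressure")


@dataclass(frozen=True)
class RecordAnalysis:
    """Compliance/modulus estimates of one record at a pressure pair."""

    lam_z: float
    ps: float
    pd: float
    C: float  # mL/mmHg per metre of vessel
    E: float  # MPa
    Ds: float
    Dd: float
    hs: float
    hd: float


def _fit_inner_line(rec: InflationRecord) -> Tuple[float, float]:
    """Least-squares line inner_d ~ pressure (slope mm/mmHg, intercept mm).

    Within the linear-elastic physiological window the pressure-diameter
    relation is linear, so the fit both denoises measured sweeps and is
    exact on noiseless ones.
    """
    slope, intercept = np.polyfit(rec.pressures, rec.inner_d, 1)
    return float(slope), float(intercept)


def analyze_record(rec: InflationRecord, ps: float = 113.0, pd_: float = 60.0) -> RecordAnalysis:
    """Compliance and circumferential modulus of a record at pressures (ps, pd).

    Inner diameters at the requested pressures come from the least-squares
    pressure-diameter line (exact for noiseless sweeps); thicknesses are
    linearly interpolated between samples. Both pressures must lie inside
    the sampled range. A (near-)constant diameter sweep means infinite
    stiffness and raises a validation error.
    """
    lo, hi = rec.pressures[0], rec.pressures[-1]
    if not (lo <= pd_ < ps <= hi):
        raise ExtrapolationError(
            f"requested pressures {ps}/{pd_} mmHg outside sampled range [{lo}, {hi}]"
        )
    slope, intercept = _fit_inner_line(rec)
    Ds = slope * ps + intercept
    Dd = slope * pd_ + intercept
    if Ds - Dd <= 1e-9 * rec.Do:
        raise ValidationError("no measurable distension between ps and pd: modulus diverges")
    hs = float(np.interp(ps, rec.pressures, rec.thickness))
    hd = float(np.interp(pd_, rec.pressures, rec.thickness))
    geom = ArterialGeometry(Ds=Ds, Dd=Dd, hs=min(hs, hd), hd=hd, Do=rec.Do, lam_z=rec.lam_z)
    pstate = PressureState(ps=ps, pd=pd_)
    from .core import circ_modulus, compliance

    return RecordAnalysis(
        lam_z=rec.lam_z, ps=ps, pd=pd_,
        C=compliance(geom, pstate), E=circ_modulus(geom, pstate),
        Ds=Ds, Dd=Dd, hs=hs, hd=hd,
    )


# ---------------------------------------------------------------------------
# synthetic generator


def default_modulus_law(lam_z: float, e_base: float = 0.30, rate: float = 1.9) -> float:
    """Circumferential modulus (MPa) vs axial pre-stretch for the synthetic family.

    Exponential stiffening as pre-stretch is lost: E = e_base *
    exp(rate * (1.33 - lam_z)), giving ~0.30 MPa at lam_z = 1.33 (young,
    compliant) up to ~0.55 MPa at 1.01 (aged), with the steepest change at
    low lam_z, the porcine-scale counterpart of accelerated late-life
    stiffening. The values sit well below human thoracic moduli
    (~0.7-1.4 MPa), as porcine vessels do.
    """
    return e_base * math.exp(rate * (1.33 - lam_z))


@dataclass(frozen=True)
class GeneratorConfig:
    """Synthetic stretch-inflation protocol.

    Defaults emulate the porcine bench protocol: pre-stretch ratios
    {1.33, 1.23, 1.08, 1.05, 1.01}, pressure sweep 60-120 mmHg in 5 mmHg
    steps, a ~22 mm unloaded inner diameter with a 2 mm wall, analysis
    pressures at the normal porcine 113/60 mmHg, and 0.05 mm Gaussian noise
    on the outer-diameter readings (laser rangefinder scale). The modulus
    law must be monotone increasing with decreasing lam_z when the aging
    profile is requested.
    """

    lam_z: Sequence[float] = (1.33, 1.23, 1.08, 1.05, 1.01)
    p_min: float = 60.0
    p_max: float = 120.0
    p_step: float = 5.0
    d_ref: float = 22.0  # mm, unloaded inner diameter at lam_z = 1
    h_ref: float = 1.5  # mm, unloaded wall thickness at lam_z = 1
    dia_strain: float = 0.10  # circumferential strain already present at p_min
    ps_ref: float = 113.0
    pd_ref: float = 60.0
    phi: float = 0.04  # perivascular constraint of the bench mounting
    noise_sd: float = 0.05  # mm, on outer diameter only
    modulus_law: Callable[[float], float] = field(default=default_modulus_law)
    require_aging: bool = True

    def pressure_grid(self) -> np.ndarray:
        n = int(round((self.p_max - self.p_min) / self.p_step))
        return self.p_min + self.p_step * np.arange(n + 1)


def _unloaded_geometry(cfg: GeneratorConfig, lam_z: float) -> Tuple[float, float]:
    """Unloaded inner diameter and thickness at this pre-stretch, mm.

    The wall is axially incompressible: stretching it by lam_z thins both
    dimensions by 1/sqrt(lam_z).
    """
    return cfg.d_ref / math.sqrt(lam_z), cfg.h_ref / math.sqrt(lam_z)


def _noiseless_record(cfg: GeneratorConfig, lam_z: float, slope: float) -> InflationRecord:
    """Linear pressure-diameter tube with an axially incompressible wall.

    The inner diameter rises linearly from its pre-distended value at the
    bottom of the sweep (``slope`` in mm/mmHg); the outer diameter follows
    from conservation of the wall annulus, so the thickness thins with
    pressure. The nonlinear toe region below ``p_min`` is not modelled; the
    unloaded diameter enters only as the strain reference Do.
    """
    d0, h0 = _unloaded_geometry(cfg, lam_z)
    w = (d0 + 2 * h0) ** 2 - d0**2  # conserved wall annulus (area * 4/pi)
    p = cfg.pressure_grid()
    inner = d0 * (1.0 + cfg.dia_strain) + slope * (p - cfg.p_min)
    outer = np.sqrt(inner**2 + w)
    thick = (outer - inner) / 2.0
    return InflationRecord(lam_z=lam_z, pressures=p, outer_d=outer, thickness=thick, Do=d0)


def _solve_slope(cfg: GeneratorConfig, lam_z: float, e_target: float) -> float:
    """Distension slope (mm/mmHg) whose analyzed modulus at (ps_ref, pd_ref) is e_target.

    With the diastolic diameter anchored at the bottom of the sweep the
    thin-wall modulus is exactly inversely proportional to the slope, so the
    inversion is closed form.
    """
    if cfg.pd_ref != cfg.p_min:
        # general case: anchor moved; fall back to root finding
        def err(c: float) -> float:
            rec = _noiseless_record(cfg, lam_z, c)
            return analyze_record(rec, cfg.ps_ref, cfg.pd_ref).E - e_target

        return brentq(err, 1e-8, 10.0, xtol=1e-15, rtol=8.9e-16)
    d0, h0 = _unloaded_geometry(cfg, lam_z)
    w = (d0 + 2 * h0) ** 2 - d0**2
    dd = d0 * (1.0 + cfg.dia_strain)
    hd = (math.sqrt(dd**2 + w) - dd) / 2.0
    p_pa = mmhg_to_pa((2.0 * cfg.pd_ref + cfg.ps_ref) / 3.0)
    return dd * p_pa * d0 / (2.0 * hd * (cfg.ps_ref - cfg.pd_ref) * mpa_to_pa(e_target))


def generate_synthetic(
    cfg: Optional[GeneratorConfig] = None, seed: int = 0
) -> List[InflationRecord]:
    """Deterministic synthetic stretch-inflation family, one record per lam_z.

    The noiseless records satisfy all record invariants and invert exactly
    under :func:`analyze_record` (the generator solves for the distension
    slope that reproduces the imposed modulus law); Gaussian noise of
    ``cfg.noise_sd`` mm is then added to the outer-diameter readings only.
    """
    cfg = cfg or GeneratorConfig()
    e_vals = [cfg.modulus_law(l) for l in cfg.lam_z]
    if cfg.require_aging:
        order = sorted(range(len(cfg.lam_z)), key=lambda i: -cfg.lam_z[i])
        es = [e_vals[i] for i in order]
        if any(b <= a for a, b in zip(es, es[1:])):
            raise ValidationError(
                "aging profile requires a modulus law strictly increasing as lam_z decreases"
            )
    rng = np.random.default_rng(seed)
    records = []
    for lam, e in zip(cfg.lam_z, e_vals):
        slope = _solve_slope(cfg, lam, e)
        rec = _noiseless_record(cfg, lam, slope)
        rec.check_monotone()
        if cfg.noise_sd > 0:
            outer = rec.outer_d + rng.normal(0.0, cfg.noise_sd, size=rec.outer_d.shape)
            rec = InflationRecord(
                lam_z=lam, pressures=rec.pressures, outer_d=outer,
                thickness=rec.thickness, Do=rec.Do,
            )
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# SEDI surfaces and aging curves


@dataclass(frozen=True)
class SediSurface:
    """Strain-energy density increment over a (ps, pd) grid for one record."""

    lam_z: float
    ps_grid: np.ndarray
    pd_grid: np.ndarray
    du: np.ndarray  # J/m^3, NaN where ps <= pd
    max_du: float
    argmax: Tuple[float, float]  # (ps, pd) of the maximum


def sedi_surface(
    rec: InflationRecord,
    phi: float = 0.04,
    E: Optional[float] = None,
    ps_grid: Optional[np.ndarray] = None,
    pd_grid: Optional[np.ndarray] = None,
    pd_min: Optional[float] = None,
) -> SediSurface:
    """Evaluate the SEDI over a systolic/diastolic pressure grid.

    alpha_s and alpha_d are taken from the record (diameter/thickness at each
    grid pressure, denoised through the fitted pressure-diameter line); E
    defaults to the record's analyzed modulus. Cells with ps <= pd (or below
    ``pd_min``) are masked. The surface is non-negative and vanishes on the
    locus alpha_s*ps = alpha_d*pd.
    """
    lo, hi = rec.pressures[0], rec.pressures[-1]
    if ps_grid is None:
        ps_grid = np.linspace(lo, hi, 25)
    if pd_grid is None:
        pd_grid = np.linspace(lo, hi, 25)
    ps_grid = np.asarray(ps_grid, dtype=float)
    pd_grid = np.asarray(pd_grid, dtype=float)
    if ps_grid.min() < lo or ps_grid.max() > hi or pd_grid.min() < lo or pd_grid.max() > hi:
        raise ExtrapolationError("SEDI grid extends outside the sampled pressure range")
    if E is None:
        E = analyze_record(rec, ps=min(113.0, hi), pd_=max(60.0, lo)).E
    slope, intercept = _fit_inner_line(rec)
    d_of = lambda p: slope * p + intercept
    h_of = lambda p: np.interp(p, rec.pressures, rec.thickness)
    mech = WallMechanics(E=E, phi=phi)
    du = np.full((ps_grid.size, pd_grid.size), np.nan)
    best = (-math.inf, None)
    for i, ps in enumerate(ps_grid):
        for j, pd_ in enumerate(pd_grid):
            if ps <= pd_ or (pd_min is not None and pd_ < pd_min):
                continue
            geom = ArterialGeometry(
                Ds=d_of(ps), Dd=d_of(pd_), hs=float(h_of(ps)), hd=float(h_of(pd_)),
                Do=rec.Do, lam_z=rec.lam_z,
            )
            val = sedi(PressureState(ps=ps, pd=pd_), geom, mech)
            du[i, j] = val
            if val > best[0]:
                best = (val, (float(ps), float(pd_)))
    if best[1] is None:
        raise ValidationError("empty valid (ps > pd) region on the SEDI grid")
    return SediSurface(
        lam_z=rec.lam_z, ps_grid=ps_grid, pd_grid=pd_grid, du=du,
        max_du=best[0], argmax=best[1],
    )


@dataclass(frozen=True)
class AgingCurve:
    """Compliance, modulus and peak SEDI along the pre-stretch (aging) axis."""

    lam_z: np.ndarray
    C: np.ndarray
    E: np.ndarray
    max_sedi: np.ndarray
    argmax: List[Tuple[float, float]]


def build_aging_curve(
    records: Sequence[InflationRecord],
    ps: float = 113.0,
    pd_: float = 60.0,
    phi: float = 0.04,
) -> AgingCurve:
    """Analyze a family of records into the aging trends.

    On the noiseless synthetic family, compliance strictly decreases and
    modulus strictly increases as lam_z decreases, and the peak SEDI shrinks
    with lam_z: the aged, stiff vessel stores less drive energy.
    """
    recs = sorted(records, key=lambda r: -r.lam_z)
    lam = np.array([r.lam_z for r in recs])
    C, E, mx, am = [], [], [], []
    for r in recs:
        a = analyze_record(r, ps, pd_)
        surf = sedi_surface(r, phi=phi, E=a.E)
        C.append(a.C)
        E.append(a.E)
        mx.append(surf.max_du)
        am.append(surf.argmax)
    return AgingCurve(lam_z=lam, C=np.array(C), E=np.array(E), max_sedi=np.array(mx), argmax=am)


# ---------------------------------------------------------------------------
# CSV I/O (columns: lam_z, pressure_mmHg, outer_diameter_mm, thickness_mm, do_mm)


def records_to_csv(records: Sequence[InflationRecord]) -> str:
    frames = []
    for r in records:
        frames.append(
            pd.DataFrame(
                {
                    "lam_z": r.lam_z,
                    "pressure_mmHg": r.pressures,
                    "outer_diameter_mm": r.outer_d,
                    "thickness_mm": r.thickness,
                    "do_mm": r.Do,
                }
            )
        )
    return pd.concat(frames, ignore_index=True).to_csv(index=False)


def records_from_csv(path_or_buf) -> List[InflationRecord]:
    if isinstance(path_or_buf, str) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    df = pd.read_csv(path_or_buf)
    required = {"lam_z", "pressure_mmHg", "outer_diameter_mm", "thickness_mm", "do_mm"}
    missing = required - set(df.columns)
    if missing:
        from .errors import SchemaError

        raise SchemaError(f"record CSV is missing columns: {', '.join(sorted(missing))}")
    records = []
    for lam, sub in df.groupby("lam_z", sort=False):
        sub = sub.sort_values("pressure_mmHg")
        records.append(
            InflationRecord(
                lam_z=float(lam),
                pressures=sub["pressure_mmHg"].to_numpy(float),
                outer_d=sub["outer_diameter_mm"].to_numpy(float),
                thickness=sub["thickness_mm"].to_numpy(float),
                Do=float(sub["do_mm"].iloc[0]),
            )
        )
    return records
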