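"""Orthostatic-hypotension scenario engine and carotid-stenosis analysis.

A scenario is a blood-pressure drop applied to an age-specific baseline;
the onset of orthostatic hypotension is fast relative to vascular
remodelling, so geometry, rheology, stiffness and pre-stretch are held at
their baseline values and only the pressures move. The published grid uses
a slightly different constraint coefficient (and, in the 80-y group, a
different beta) for the perturbed orthostatic states than for the resting
baseline; those values are honored as given, and apply whenever a nonzero
drop is requested. The identity scenario (zero drop) reproduces the
baseline column exactly.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Dict, List, Optional

import pandas as pd

from . import table1
from .core import solve_flow
from .errors import ValidationError
from .params import ArterialGeometry, FlowSolution, PressureState, WallMechanics
from .table1 import ColumnParams, column_params, group_columns

#: published degree-of-stenosis -> remaining flow-area ratio map
DEGREE_AREA_RATIO: Dict[int, float] = {0: 1.0, 50: 0.50, 70: 0.374, 80: 0.312, 90: 0.252}

ROUNDING = {"P": 1, "V": 3, "Q": 3, "Qbar": 2, "delta_pct": 2}


@dataclass(frozen=True)
class ScenarioSpec:
    """A BP-drop scenario against a named baseline.

    ``baseline`` is a group label ("60y"/"80y") or a column label of the
    parameter grid; ``d_sbp``/``d_dbp`` are non-negative drops in mmHg;
    ``reference`` names the baseline the percent change is computed against
    (defaults to the scenario's own baseline).
    """

    label: str
    baseline: str = "60y"
    d_sbp: float = 0.0
    d_dbp: float = 0.0
    reference: Optional[str] = None

    def __post_init__(self) -> None:
        if self.d_sbp < 0 or self.d_dbp < 0:
            raise ValidationError("pressure drops must be non-negative")


@dataclass(frozen=True)
class StenosisSpec:
    """Carotid stenosis degree with its remaining flow-area ratio in (0, 1]."""

    degree: float
    area_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 < self.area_ratio <= 1.0):
            raise ValidationError(f"area ratio must be in (0, 1], got {self.area_ratio}")

    @classmethod
    def from_degree(cls, degree: int) -> "StenosisSpec":
        try:
            return cls(degree=degree, area_ratio=DEGREE_AREA_RATIO[int(degree)])
        except KeyError:
            raise ValidationError(
                f"no published area ratio for {degree}% stenosis; "
                f"known degrees: {sorted(DEGREE_AREA_RATIO)}"
            ) from None


@dataclass(frozen=True)
class ScenarioResult:
    label: str
    pstate: PressureState
    solution: FlowSolution
    reference_label: str
    reference_qbar: float
    delta_pct: float


def _resolve_baseline(inputs: pd.DataFrame, name: str) -> str:
    if name in table1.GROUPS:
        return table1.GROUPS[name]
    if name in inputs.columns:
        return name
    raise ValidationError(f"unknown baseline {name!r}")


def _orthostatic_overrides(inputs: pd.DataFrame, base_label: str) -> ColumnParams:
    """Parameters for perturbed states of a group: the grid's non-baseline phi/beta."""
    group = "60y" if base_label == table1.GROUPS["60y"] else "80y"
    labels = group_columns(inputs, group)
    scen = [l for l in labels if l != base_label]
    base = column_params(inputs, base_label)
    if not scen:
        return base
    col = column_params(inputs, scen[0])
    return replace(base, mech=WallMechanics(E=base.mech.E, phi=col.mech.phi,
                                            beta=col.beta_printed))


def _solve_column(col: ColumnParams, pstate: Optional[PressureState] = None) -> FlowSolution:
    return solve_flow(pstate or col.pstate, col.geom, col.mech, col.rheo, col.n)


def run_scenario(spec: ScenarioSpec, inputs: Optional[pd.DataFrame] = None) -> ScenarioResult:
    """Compute the flow solution of a BP-drop scenario and its percent change.

    delta% is computed from unrounded mean flows:
    100 * (Qbar_scenario - Qbar_reference) / Qbar_reference.
    """
    if inputs is None:
        inputs = table1.load_inputs()
    base_label = _resolve_baseline(inputs, spec.baseline)
    base = column_params(inputs, base_label)
    ps = base.pstate.ps - spec.d_sbp
    pd_ = base.pstate.pd - spec.d_dbp
    if not ps > pd_:
        raise ValidationError(
            f"drop leaves no pulse pressure: {ps}/{pd_} mmHg after "
            f"-{spec.d_sbp}/-{spec.d_dbp}"
        )
    perturbed = spec.d_sbp > 0 or spec.d_dbp > 0
    col = _orthostatic_overrides(inputs, base_label) if perturbed else base
    sol = _solve_column(col, PressureState(ps=ps, pd=pd_))

    ref_label = _resolve_baseline(inputs, spec.reference) if spec.reference else base_label
    ref_sol = _solve_column(column_params(inputs, ref_label))
    delta = 100.0 * (sol.Qbar / ref_sol.Qbar - 1.0)
    return ScenarioResult(
        label=spec.label, pstate=PressureState(ps=ps, pd=pd_), solution=sol,
        reference_label=ref_label, reference_qbar=ref_sol.Qbar, delta_pct=delta,
    )


def cross_reference(
    spec_a: ScenarioSpec, spec_b: ScenarioSpec, inputs: Optional[pd.DataFrame] = None
) -> float:
    """Percent change of scenario a's mean flow relative to scenario b's."""
    if inputs is None:
        inputs = table1.load_inputs()
    a = run_scenario(spec_a, inputs)
    b = run_scenario(spec_b, inputs)
    return 100.0 * (a.solution.Qbar / b.solution.Qbar - 1.0)


def apply_stenosis(
    spec: StenosisSpec,
    baseline: str = "60y",
    mode: str = "recomputed",
    inputs: Optional[pd.DataFrame] = None,
) -> float:
    """Percent change of CBF under a carotid flow-area reduction.

    "proportional": CBF scales with the remaining area, delta = 100*(ratio-1).
    "recomputed" (default): the lumen diameters are rescaled by sqrt(ratio)
    at fixed wall thickness, the dissipation coefficient rescaled with 1/D,
    and the flow re-solved; this is more severe than proportional because a
    narrower lumen at fixed wall raises the dissipation coefficient. Both
    modes return 0 at ratio 1. Reported as a percent change because no
    carotid geometry column is published.
    """
    if mode == "proportional":
        return 100.0 * (spec.area_ratio - 1.0)
    if mode != "recomputed":
        raise ValidationError(f"unknown stenosis mode {mode!r}")
    if inputs is None:
        inputs = table1.load_inputs()
    base = column_params(inputs, _resolve_baseline(inputs, baseline))
    sol0 = _solve_column(base)
    s = math.sqrt(spec.area_ratio)
    g = base.geom
    geom_s = ArterialGeometry(
        Ds=s * g.Ds, Dd=s * g.Dd, hs=g.hs, hd=g.hd,
        Dso=s * g.Ds + 2 * g.hs, Ddo=s * g.Dd + 2 * g.hd,
        lam_z=g.lam_z, eps_Ap=g.eps_Ap,
    )
    beta_s = sol0.beta / s  # beta ~ 1/D at fixed wall, friction and pulse pressure
    mech_s = WallMechanics(E=base.mech.E, phi=base.mech.phi, beta=beta_s)
    sol_s = solve_flow(base.pstate, geom_s, mech_s, base.rheo, base.n)
    return 100.0 * (sol_s.Qbar / sol0.Qbar - 1.0)


def load_published_stenosis() -> pd.DataFrame:
    """Published degree / area-ratio / delta-CBF table (for residual reporting)."""
    with resources.files("aortaflow.data").joinpath("stenosis_published.csv").open() as fh:
        return pd.read_csv(fh)


def stenosis_report(baseline: str = "60y", inputs: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Both stenosis modes vs the published delta-CBF values, with residuals.

    The derivation behind the published values is under-specified; neither
    mode reproduces them exactly, so the report carries residuals rather
    than asserting agreement.
    """
    pub = load_published_stenosis()
    rows = []
    for _, r in pub.iterrows():
        spec = StenosisSpec(degree=r["degree_pct"], area_ratio=r["area_ratio"])
        prop = apply_stenosis(spec, baseline, mode="proportional", inputs=inputs)
        reco = apply_stenosis(spec, baseline, mode="recomputed", inputs=inputs)
        rows.append(
            {
                "degree_pct": r["degree_pct"],
                "area_ratio": r["area_ratio"],
                "published_delta_cbf_pct": r["delta_cbf_pct"],
                "proportional_delta_cbf_pct": prop,
                "recomputed_delta_cbf_pct": reco,
                "proportional_residual": prop - r["delta_cbf_pct"],
                "recomputed_residual": reco - r["delta_cbf_pct"],
            }
        )
    return pd.DataFrame(rows)


def report_table(
    results: List[ScenarioResult], rounding: Optional[Dict[str, int]] = None
) -> pd.DataFrame:
    """Arrange scenario results as a symbol-by-scenario grid (reference-table shape).

    Pressures are rounded to 1 decimal, V and Q to 3, Qbar to 2, CBF floored
    to whole mL/min and delta% to 2 decimals; an empty list yields a
    header-only table and a pure baseline column leaves delta% blank.
    """
    rnd = dict(ROUNDING)
    if rounding:
        rnd.update(rounding)
    cols: Dict[str, Dict[str, object]] = {}
    for res in results:
        sol = res.solution
        lo, hi = math.floor(sol.cbf_lo), math.floor(sol.cbf_hi)
        cols[res.label] = {
            "Ps": round(res.pstate.ps, rnd["P"]),
            "Pd": round(res.pstate.pd, rnd["P"]),
            "P": round(res.pstate.pmean, rnd["P"]),
            "V": round(sol.V, rnd["V"]),
            "Q": round(sol.Q, rnd["Q"]),
            "n": sol.n,
            "Qbar": round(sol.Qbar, rnd["Qbar"]),
            "CBF": f"{lo}~{hi}",
            "delta_pct": ""
            if res.delta_pct == 0.0 and res.solution.Qbar == res.reference_qbar
            else round(res.delta_pct, rnd["delta_pct"]),
        }
    index = ["Ps", "Pd", "P", "V", "Q", "n", "Qbar", "CBF", "delta_pct"]
    return pd.DataFrame(cols, index=index if cols else index)


def format_report(df: pd.DataFrame) -> str:
    """Aligned text rendering of a report grid."""
    return df.to_string()
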