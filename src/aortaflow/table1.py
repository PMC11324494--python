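"""Bundled reference parameter table and loaders.

The package ships the published 14-column parameter grid for the ascending
aorta: a 60-year normotensive baseline (129.1/79.8 mmHg) with five
blood-pressure-drop columns, and an 80-year hypertensive baseline
(154/76 mmHg) with seven drop columns, together with the printed model
outputs (V, Q, Qbar, CBF, delta%) used for validation.

CSV layout: one row per symbol, one column per scenario. The same schema is
accepted from user files, so any cohort can be analyzed by swapping the CSV.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional

import pandas as pd

from .errors import SchemaError
from .params import ArterialGeometry, BloodRheology, PressureState, WallMechanics

INPUT_ROWS = [
    "Ps", "Pd", "lam_z", "eps_Ap", "Dso", "hs", "Ds", "Ddo", "hd", "Dd",
    "E", "phi", "Re", "n",
]
#: printed beta is bundled alongside the inputs (as-printed mode uses it)
OPTIONAL_INPUT_ROWS = ["beta"]

PRINTED_ROWS = ["P", "V", "Q", "Qbar", "CBF_lo", "CBF_hi", "delta_pct"]

#: group labels -> (baseline column, scenario columns)
GROUPS: Dict[str, str] = {"60y": "base60", "80y": "base80"}


def _read_symbol_csv(path_or_buf) -> pd.DataFrame:
    df = pd.read_csv(path_or_buf)
    if "symbol" not in df.columns:
        raise SchemaError("missing 'symbol' column")
    return df.set_index("symbol")


def load_inputs(path: Optional[str] = None) -> pd.DataFrame:
    """Load a parameter grid (bundled fixture by default); validate the schema."""
    if path is None:
        with resources.files("aortaflow.data").joinpath("table1_inputs.csv").open() as fh:
            df = _read_symbol_csv(fh)
    else:
        df = _read_symbol_csv(path)
    missing = [r for r in INPUT_ROWS if r not in df.index]
    if missing:
        raise SchemaError(f"parameter table is missing rows: {', '.join(missing)}")
    return df.astype(float)


def load_printed() -> pd.DataFrame:
    """Printed model outputs of the bundled reference table."""
    with resources.files("aortaflow.data").joinpath("table1_printed.csv").open() as fh:
        df = _read_symbol_csv(fh)
    missing = [r for r in PRINTED_ROWS if r not in df.index]
    if missing:
        raise SchemaError(f"printed table is missing rows: {', '.join(missing)}")
    return df.astype(float)


@dataclass(frozen=True)
class ColumnParams:
    """One scenario column, unpacked into domain objects."""

    label: str
    pstate: PressureState
    geom: ArterialGeometry
    mech: WallMechanics
    rheo: BloodRheology
    n: float
    beta_printed: Optional[float]


def column_params(inputs: pd.DataFrame, label: str, K: Optional[float] = None) -> ColumnParams:
    """Unpack one column of a parameter grid into validated domain objects."""
    if label not in inputs.columns:
        raise SchemaError(f"parameter table has no column {label!r}")
    c = inputs[label]
    pstate = PressureState(ps=c["Ps"], pd=c["Pd"])
    geom = ArterialGeometry(
        Ds=c["Ds"], Dd=c["Dd"], hs=c["hs"], hd=c["hd"],
        Dso=c["Dso"], Ddo=c["Ddo"], lam_z=c["lam_z"], eps_Ap=c["eps_Ap"],
    )
    beta = float(c["beta"]) if "beta" in inputs.index else None
    mech = WallMechanics(E=c["E"], phi=c["phi"], K=K, beta=beta)
    rheo = BloodRheology(Re=c["Re"])
    return ColumnParams(
        label=label, pstate=pstate, geom=geom, mech=mech, rheo=rheo,
        n=float(c["n"]), beta_printed=beta,
    )


def group_columns(inputs: pd.DataFrame, group: str) -> List[str]:
    """Column labels of one age group, baseline first."""
    base = GROUPS[group]
    if base not in inputs.columns:
        raise SchemaError(f"parameter table has no column {base!r}")
    tag = group[:2]  # "60" / "80"
    cols = [base] + [c for c in inputs.columns if c.startswith(f"s{tag}_")]
    return cols
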