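"""Run configuration (YAML-backed).

Collects the knobs that change how reports are produced without touching
the model: material overrides (rho, g), CBF fraction bounds, the rounding
policy, the Reynolds-number mode and the beta mode, output paths and the
seed for anything stochastic (only the synthetic experiment generator).
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import yaml

from .errors import ValidationError
from .units import G_STANDARD, RHO_BLOOD

DEFAULT_ROUNDING: Dict[str, int] = {"P": 1, "V": 3, "Q": 3, "Qbar": 2, "delta_pct": 2}


@dataclass
class RunConfig:
    rho: float = RHO_BLOOD
    g: float = G_STANDARD
    cbf_fractions: Tuple[float, float] = (0.12, 0.15)
    rounding: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_ROUNDING))
    re_mode: str = "fixed"  # "fixed" | "fixed-point"
    beta_mode: str = "as-printed"  # "as-printed" | "self-consistent"
    out_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cbf_fractions
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError(f"CBF fractions must be ordered in (0, 1), got {self.cbf_fractions}")
        if self.re_mode not in ("fixed", "fixed-point"):
            raise ValidationError(f"unknown Re mode {self.re_mode!r}")
        if self.beta_mode not in ("as-printed", "self-consistent"):
            raise ValidationError(f"unknown beta mode {self.beta_mode!r}")
        if int(self.seed) != self.seed:
            raise ValidationError("seed must be an integer")
        self.cbf_fractions = (float(lo), float(hi))

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "cbf_fractions" in data:
            data["cbf_fractions"] = tuple(data["cbf_fractions"])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["cbf_fractions"] = list(self.cbf_fractions)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
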