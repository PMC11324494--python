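"""Unit conversions.

All model arithmetic is done in SI; the public API accepts the units a
clinician or bench experimenter records: pressures in mmHg, lengths in mm,
elastic moduli in MPa, flows in L. The conversion factor 1 mmHg = 133.322 Pa
is fixed.
"""

MMHG_PA: float = 133.322
"""Pascals per mmHg."""

#: default blood density, kg/m^3
RHO_BLOOD: float = 1050.0
#: standard gravity, m/s^2
G_STANDARD: float = 9.81


def mmhg_to_pa(p: float) -> float:
    return p * MMHG_PA


def pa_to_mmhg(p: float) -> float:
    return p / MMHG_PA


def mm_to_m(x: float) -> float:
    return x * 1e-3


def m_to_mm(x: float) -> float:
    return x * 1e3


def mm2_to_m2(a: float) -> float:
    return a * 1e-6


def mpa_to_pa(e: float) -> float:
    return e * 1e6


def pa_to_mpa(e: float) -> float:
    return e * 1e-6


def m3_to_l(v: float) -> float:
    return v * 1e3


def m3_per_pa_to_ml_per_mmhg(c: float) -> float:
    """Compliance: m^3/Pa -> mL/mmHg."""
    return c * 1e6 * MMHG_PA
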