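"""Physical constants and the unit conversions used at module boundaries.

All internal computation is done in nm, nm², K and joules; the area
expansion modulus K_A is accepted and emitted in mN/m (the unit membrane
papers print) and bending rigidity κ in both joules and kBT.  Every scale
factor lives here so that a single routine owns each boundary conversion.
"""

from __future__ import annotations

#: Boltzmann constant, exact SI value (J/K).
KB = 1.380649e-23

#: 1 J/nm² expressed in mN/m:  1 J/nm² = 1e18 J/m² = 1e18 N/m = 1e21 mN/m.
_J_PER_NM2_TO_MN_PER_M = 1.0e21


def kbt_joule(temperature_k: float) -> float:
    """Thermal energy kB·T in joules at the given absolute temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature_k}")
    return KB * temperature_k


def j_per_nm2_to_mn_per_m(value: float) -> float:
    """Convert a surface modulus from J/nm² to mN/m."""
    return value * _J_PER_NM2_TO_MN_PER_M


def mn_per_m_to_j_per_nm2(value: float) -> float:
    """Convert a surface modulus from mN/m to J/nm²."""
    return value / _J_PER_NM2_TO_MN_PER_M


def joule_to_kbt(energy_j: float, temperature_k: float) -> float:
    """Express an energy in units of kB·T at the given temperature."""
    return energy_j / kbt_joule(temperature_k)


def kbt_to_joule(energy_kbt: float, temperature_k: float) -> float:
    """Convert an energy from kB·T units to joules."""
    return energy_kbt * kbt_joule(temperature_k)


def celsius_to_kelvin(temperature_c: float) -> float:
    """Convert °C to K (temperatures are accepted in °C only at the CLI/config boundary)."""
    temperature_k = temperature_c + 273.15
    if temperature_k <= 0:
        raise ValueError(f"{temperature_c} °C is at or below absolute zero")
    return temperature_k
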