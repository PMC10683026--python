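"""Physical constants and unit conversions used across the toolkit.

Structure-derived distances are reported in Angstrom (crystallographic
convention); collective variables, pull coordinates and exported MD
configuration use nanometres (MD convention). All conversions funnel
through this module so the factor appears exactly once.
"""

from __future__ import annotations

#: Molar gas constant, kJ mol^-1 K^-1 (CODATA 2018).
GAS_CONSTANT_KJ_PER_MOL_K: float = 8.314462618e-3

#: Standard thermodynamic temperature, K.
STANDARD_TEMPERATURE_K: float = 298.15

#: RT at the standard temperature, kJ mol^-1 (~2.4790).
RT_STANDARD_KJ_PER_MOL: float = GAS_CONSTANT_KJ_PER_MOL_K * STANDARD_TEMPERATURE_K

ANGSTROM_PER_NM: float = 10.0


def rt_kj_per_mol(temperature_k: float = STANDARD_TEMPERATURE_K) -> float:
    """RT in kJ/mol at the given temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return GAS_CONSTANT_KJ_PER_MOL_K * temperature_k


def angstrom_to_nm(value_angstrom):
    return value_angstrom / ANGSTROM_PER_NM


def nm_to_angstrom(value_nm):
    return value_nm * ANGSTROM_PER_NM
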