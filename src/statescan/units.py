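"""Physical constants and unit conversions.

Internal conventions: coordinates in Å, reaction coordinates in nm
(GROMACS convention), energies in kcal·mol⁻¹.  Bias force constants are
accepted in kJ·mol⁻¹·nm⁻² and converted exactly at module boundaries.
"""

R_KCAL = 0.0019872
"""Gas constant in kcal·mol⁻¹·K⁻¹."""

KJ_PER_KCAL = 4.184
"""Exact thermochemical calorie conversion."""

R_KJ = R_KCAL * KJ_PER_KCAL
"""Gas constant in kJ·mol⁻¹·K⁻¹ (derived from R_KCAL)."""

DEFAULT_TEMPERATURE = 310.0
"""Simulation temperature in K (physiological)."""


def rt_kcal(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy RT in kcal·mol⁻¹."""
    return R_KCAL * temperature


def kj_to_kcal(x):
    """Convert kJ·mol⁻¹ (or kJ-based force constants) to kcal-based units."""
    return x / KJ_PER_KCAL


def kcal_to_kj(x):
    return x * KJ_PER_KCAL
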