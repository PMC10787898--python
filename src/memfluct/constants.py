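"""Physical constants and unit helpers used across the package.

Internal convention: mechanics in SI (m, s, J, N/m, N/m^3, Pa.s); stored
heights and optical lengths in nm; tensions reported to tables in pN/um
(1 pN/um = 1e-6 N/m).
"""

K_B = 1.380649e-23
"""Boltzmann constant (J/K)."""

DEFAULT_TEMPERATURE = 300.0
"""Temperature (K) used wherever an experiment does not record one."""

NM = 1e-9
"""Metres per nanometre."""


def kBT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in joules."""
    return K_B * temperature


def kappa_default(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Membrane bending rigidity fixed at 15 k_B T (J), the value used
    throughout the analysis for both PSD fits and tether tension."""
    return 15.0 * kBT(temperature)


def tension_to_pN_per_um(sigma_N_per_m: float) -> float:
    """Convert tension from N/m to pN/um for report tables."""
    return sigma_N_per_m / 1e-6
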