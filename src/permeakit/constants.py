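"""Physical constants and unit conversions.

Energies are kcal/mol, lengths Å, times ns, voltages V, concentrations mM
throughout the package unless a function states otherwise.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL_PER_MOL_K = 0.0019872041

#: Default simulation temperature (K) for the Brownian sampler.
DEFAULT_TEMPERATURE_K = 300.0

#: Faraday constant, C mol^-1.
FARADAY_C_PER_MOL = 96485.33212

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT_J_PER_MOL_K = 8.31446261815324

#: Elementary charge, C.
ELEMENTARY_CHARGE_C = 1.602176634e-19

#: 1 kcal mol^-1 e^-1 expressed as a potential difference in volts.
#: (4184 J/mol) / (96485.33 C/mol) = 0.0433641 V.
KCAL_PER_MOL_E_TO_VOLT = 4184.0 / FARADAY_C_PER_MOL


def thermal_energy(temperature_k: float = DEFAULT_TEMPERATURE_K) -> float:
    """k_B*T in kcal/mol at the given temperature."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return KB_KCAL_PER_MOL_K * temperature_k


def thermal_voltage(temperature_k: float) -> float:
    """RT/F in volts (~25.7 mV at 298.15 K)."""
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    return GAS_CONSTANT_J_PER_MOL_K * temperature_k / FARADAY_C_PER_MOL
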