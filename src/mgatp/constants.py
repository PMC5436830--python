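"""Physical constants and unit conversions used across the package."""

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Boltzmann constant in kJ/(mol K).
KB_KJ_PER_MOL_K = 0.008314462618

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = KB_KJ_PER_MOL_K / KJ_PER_KCAL

#: Simulation temperature (K) assumed when work files carry energy units.
DEFAULT_TEMPERATURE_K = 300.0


def beta(temperature_k: float = DEFAULT_TEMPERATURE_K, unit: str = "kJ/mol") -> float:
    """Inverse thermal energy 1/(k_B T) for energies in ``unit``.

    Parameters
    ----------
    temperature_k:
        Absolute temperature in Kelvin.
    unit:
        ``"kJ/mol"`` or ``"kcal/mol"``; sets the energy unit that beta
        multiplies.
    """
    if temperature_k <= 0:
        raise ValueError(f"temperature must be positive, got {temperature_k}")
    if unit == "kJ/mol":
        kb = KB_KJ_PER_MOL_K
    elif unit == "kcal/mol":
        kb = KB_KCAL_PER_MOL_K
    else:
        raise ValueError(f"unknown energy unit {unit!r}")
    return 1.0 / (kb * temperature_k)
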