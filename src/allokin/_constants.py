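"""Physical constants shared across the package."""

#: Gas constant in kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 8.314e-3

#: Default assay temperature (37 degC), kelvin.
DEFAULT_TEMPERATURE_K = 310.15


def rt(temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """RT in kJ/mol at the given temperature."""
    return R_KJ_PER_MOL_K * temperature_K
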