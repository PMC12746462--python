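"""Physical constants."""

#: Boltzmann constant in kJ/mol/K.
KB: float = 0.0083144621

#: Default simulation temperature in kelvin.
DEFAULT_TEMPERATURE: float = 300.0
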