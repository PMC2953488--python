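"""Physical constants and shared defaults (units: Å, kcal/mol, K)."""

#: Boltzmann constant in kcal/mol/K.
KB = 0.0019872041

#: Default simulation temperature in K.
DEFAULT_TEMPERATURE = 300.0
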