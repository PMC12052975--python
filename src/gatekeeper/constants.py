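"""Physical constants."""

#: Boltzmann constant in kJ/mol/K (fixed; all energies are kJ/mol)
KB = 0.0083144621
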