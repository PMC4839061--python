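"""Physical constants (CODATA), fixed and not user-configurable."""

#: Universal gas constant, J mol^-1 K^-1
R = 8.314

#: Avogadro constant, mol^-1
N_A = 6.02214076e23
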