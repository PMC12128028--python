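"""Physical constants and default unit conventions.

Energies are kJ/mol, lengths nm, angles degrees at the API surface and
radians internally, temperatures K. Time is measured in reduced "toy" units
in which the overdamped friction coefficient is 1; one *schedule unit* (the
analog of 1 ns of the all-atom protocol) corresponds to
``steps_per_unit * dt`` toy-time units.
"""

KB = 0.008314462618  # kJ/mol/K
T_PHYS = 300.0       # physical bath temperature, K
KBT = KB * T_PHYS    # ≈ 2.494 kJ/mol
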