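# Reconstructed reference physiology for a 71 kg adult human.
# Volumes in mL, flows in mL/h. All entries are overridable defaults.
species_id: human
BW: 71.0
V_plasma: 3480.0
V_liver_vasc: 180.0
V_liver_int: 360.0
V_liver_cell: 1260.0  # total liver ~1.8 L
V_kidney: 310.0
V_remainder: 36000.0
Q_liver: 48600.0      # ~810 mL/min hepatic plasma flow
Q_kidney: 36000.0     # ~600 mL/min renal plasma flow
Q_remainder: 90000.0
lymph_fraction: 0.002
sigma_V: 0.95
sigma_I: 0.20
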