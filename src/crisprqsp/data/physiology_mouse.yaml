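# Reconstructed reference physiology for a 28 g mouse.
# Volumes in mL, flows in mL/h. All entries are overridable defaults.
species_id: mouse
BW: 0.028
V_plasma: 1.37        # ~4.9% of body weight
V_liver_vasc: 0.13
V_liver_int: 0.26
V_liver_cell: 0.91    # total liver ~1.3 mL
V_kidney: 0.34
V_remainder: 15.0
Q_liver: 59.0         # hepatic plasma flow
Q_kidney: 43.0        # renal plasma flow
Q_remainder: 360.0
lymph_fraction: 0.002
sigma_V: 0.95
sigma_I: 0.20
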