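# Reconstructed reference physiology for a 5 kg cynomolgus monkey.
# Volumes in mL, flows in mL/h. All entries are overridable defaults.
species_id: nhp
BW: 5.0
V_plasma: 245.0
V_liver_vasc: 13.5
V_liver_int: 27.0
V_liver_cell: 94.5    # total liver ~135 mL
V_kidney: 25.0
V_remainder: 2600.0
Q_liver: 9900.0
Q_kidney: 7900.0
Q_remainder: 21800.0
lymph_fraction: 0.002
sigma_V: 0.95
sigma_I: 0.20
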