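# Drug-specific rate constants, mouse (28 g). Units: 1/h unless noted.
# status: how each symbol was treated in the stepwise mouse calibration.
species_id: mouse
parameters:
  k_in_endo:   {value: 0.14, status: fixed}       # scaled from NHP, allometric exponent -0.25
  k_out_exo:   {value: 6.84, status: estimated}
  k_deg_DR:    {value: 2.04, status: fixed}       # assumed same as NHP
  LDL_tot:     {value: 539.0, status: fixed, unit: ug/mL}
  k_dis:       {value: 0.47, status: fixed}       # from the reduced mechanistic model
  k_ass:       {value: 1550.34, status: fixed}
  k_release:   {value: 0.0056, status: fixed}
  k_deg_LNP:   {value: 1.6486, status: fixed}
  k_el:        {value: 0.231, status: fixed}      # from LDL receptor half-life
  k_deg_sgRNA: {value: 0.378, status: fixed}      # tied to k_deg_mRNA
  k_deg_mRNA:  {value: 0.378, status: estimated}
  k_off_RNP:   {value: 0.00188, status: fixed}
  KD:          {value: 0.49, status: fixed, unit: nM}
  k_int:       {value: 0.9063, status: fixed}
  k_on_LNP:    {value: 0.18, status: fixed, unit: per(ug/mL)/h}
  k_off_LNP:   {value: 33.12, status: fixed}
  fu_LNP:      {value: 0.002, status: fixed}
  fu_RNA:      {value: 0.15, status: fixed}
  k_trans:     {value: 0.36, status: fixed}
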