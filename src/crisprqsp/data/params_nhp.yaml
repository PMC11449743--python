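# Drug-specific rate constants, NHP (5 kg). Units: 1/h unless noted.
species_id: nhp
parameters:
  k_in_endo:   {value: 0.039, status: estimated}
  k_out_exo:   {value: 2690.0, status: estimated}
  k_deg_DR:    {value: 2.04, status: estimated}
  LDL_tot:     {value: 539.0, status: estimated, unit: ug/mL}
  k_dis:       {value: 8.64, status: estimated}
  k_ass:       {value: 5.06, status: estimated}
  k_release:   {value: 0.634, status: estimated}
  k_deg_LNP:   {value: 1.6486, status: fixed}
  k_el:        {value: 0.231, status: fixed}
  k_deg_sgRNA: {value: 2.01, status: fixed}
  k_deg_mRNA:  {value: 0.1232, status: fixed}
  k_off_RNP:   {value: 0.00188, status: fixed}
  KD:          {value: 0.49, status: fixed, unit: nM}
  k_int:       {value: 0.9063, status: fixed}
  k_on_LNP:    {value: 0.18, status: fixed, unit: per(ug/mL)/h}
  k_off_LNP:   {value: 33.12, status: fixed}
  fu_LNP:      {value: 0.002, status: fixed}
  fu_RNA:      {value: 0.15, status: fixed}
  k_trans:     {value: 0.36, status: fixed}
pd:
  ttr:
    TTR0: 100.0
    k_out_TTR: 0.493   # 1/d
    Imax: 0.961
    IC50: 4.77         # ug/mL
    gamma: 0.31
  pcsk9:
    PCSK9_0: 100.0
    MTT: 14.5          # d
    n_transit: 3
    Imax_P: 0.771
    IC50_P: 21.5       # ug/mL
    gamma_P: 1.1
  ldl:
    LDL0: 100.0
    Gamma_LDL: 0.672
    k_deg_LDL: 4.66    # 1/d
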