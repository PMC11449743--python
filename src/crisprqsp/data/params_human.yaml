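# Drug-specific rate constants, human (71 kg). Units: 1/h unless noted.
species_id: human
parameters:
  k_in_endo:   {value: 0.007, status: estimated}
  k_out_exo:   {value: 775.0, status: estimated}
  k_deg_DR:    {value: 5.15, status: estimated}
  LDL_tot:     {value: 84.5, status: estimated, unit: ug/mL}
  k_dis:       {value: 0.186, status: estimated}
  k_ass:       {value: 56.8, status: estimated}
  k_release:   {value: 0.0056, status: fixed}
  k_deg_LNP:   {value: 0.101, status: estimated}
  k_el:        {value: 0.009, status: estimated}
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
    k_out_TTR: 0.247   # 1/d
    Imax: 0.959
    IC50: 0.3          # ug/mL
    gamma: 0.31        # no printed human value; carried over from the NHP estimate
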