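# crisprqsp

Translational quantitative-systems-pharmacology pipeline for LNP-delivered
CRISPR-Cas9 therapies: whole-body disposition of the three co-dosed
components (lipid nanoparticle, sgRNA, Cas9 mRNA) in mouse, cynomolgus
monkey and human, coupled to serum-biomarker pharmacodynamics (TTR
indirect response; PCSK9 transit/feedback; LDL-C precursor model), with

* a stiff-ODE simulation engine (bolus and 2-h infusion regimens, dense
  output, AUC, observation mapping to a registered output vocabulary),
* fixed-effect maximum-likelihood calibration with a proportional error
  model (`Var_i = sigma_slope * Y_i^2`), staged fixed/estimated parameter
  masks, multi-start, and Hessian-based relative standard errors,
* Sobol global sensitivity analysis (Saltelli design, first/total-order
  indices, bootstrap CIs, signed Spearman correlations),
* virtual-population Monte Carlo (lognormal inter-subject variability,
  per-arm response quantiles), and
* a synthetic-study generator reproducing the published sampling designs,
  used for parameter-recovery exercises.

## Model sketch

The PK core tracks amounts (ug) of free and opsonized LNP, sgRNA and mRNA in
plasma and the liver vascular space, an MPS pool, liver-interstitial free
LNP / LDL-receptor complex / released RNA, liver-cellular sgRNA, mRNA, Cas9
and ribonucleoprotein (RNP), the free LDL receptor (ug/mL), kidney pools for
LNP and sgRNA only, and a lumped remainder. Processes: reversible
opsonization, MPS phagocytosis and degradation, lumped
endocytosis/exocytosis plus single-pore convective lymph transport with
reflection coefficients, receptor binding/turnover, cargo release,
translation, RNP assembly (`k_on = k_off / KD`), RNA degradation and renal
filtration. Lymph flow is 0.2% of each organ's plasma flow. The liver-cell
RNP concentration drives the biomarker models one-way.

Parameter tables and physiology files are bundled per species under
`src/crisprqsp/data/` (YAML, fully overridable). Physiological volumes and
flows are reconstructed reference values; drug-specific constants follow the
published estimates.

## CLI

All commands take one YAML config and write CSV/JSON outputs plus a
`manifest.json` (config hash, seed, version):

```bash
crisprqsp designs                  # list bundled study designs
crisprqsp simulate sim.yaml        # forward PK/PD simulation
crisprqsp synth synth.yaml         # synthetic study bundle (obs + truth)
crisprqsp fit fit.yaml             # staged MLE calibration
crisprqsp gsa gsa.yaml             # Sobol sensitivity of exposure AUC
crisprqsp population pop.yaml      # virtual-population TTR dose-response
crisprqsp report report.yaml       # observed-vs-predicted diagnostics
```

Example `sim.yaml`:

```yaml
species: human
regimen: {dose_mgkg: 1.0, route: infusion, duration_h: 2}
pd: ttr
t_grid: {start: 0, stop_h: 672, n: 113}
outdir: results/sim_human
```

## Notes

* Biomarker states are integrated as deviations from baseline so responses
  far below the 100% scale's absolute tolerance stay resolved; observables
  are reported on the usual percent-of-baseline scale.
* The reconstructed exposure at published doses leaves the PD models
  sub-saturating; Imax and IC50 are then only jointly identifiable, which
  the calibration surfaces through large RSEs when both are estimated.
* `ModelOptions` exposes structural switches (cellular exocytosis,
  opsonization in plasma, renal clearance, receptor-cargo delivery
  fraction) with documented defaults.
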