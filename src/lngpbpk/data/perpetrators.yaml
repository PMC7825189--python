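# Perpetrator compounds: reduced one-compartment PK representations plus
# CYP3A4/SHBG interaction parameters.
#
# Provenance: interaction potencies and PK constants are transcribed from
# the open perpetrator PBPK model literature (rifampicin, itraconazole and
# clarithromycin from the Hanke et al. 2018 CYP3A4/P-gp DDI network and its
# sources; carbamazepine and efavirenz induction from published hepatocyte
# induction data and their PBPK implementations).  Steady-state average
# concentrations implied by the PK blocks were checked against published
# clinical exposures at the standard regimens.  These values are fixed
# inputs and are never adjusted against DDI outcome data.
#
# PK block: one-compartment with first-order absorption.
#   ka_1_h [1/h], v_l [L], cl_l_h [L/h] (apparent systemic), f_oral
#   [fraction reaching the systemic circulation], fu [plasma unbound
#   fraction].  Interaction drivers are unbound plasma concentrations
#   (µmol/L); enzyme-turnover targets distinguish liver and gut pools.

rifampicin:
  molecular_weight: 822.9
  pk: {ka_1_h: 1.0, v_l: 42.0, cl_l_h: 8.0, f_oral: 0.9, fu: 0.17}
  standard_doses_mg: [600]
  interactions:
    - target: cyp3a4
      mechanism: induction
      emax_fold: 10.0          # maximal fold-increase of CYP3A4 synthesis
      ec50: 0.34               # µmol/L unbound
    - target: cyp3a4
      mechanism: competitive
      ki: 18.5                 # µmol/L unbound (weak, included for completeness)
    - target: shbg_synthesis
      mechanism: induction
      emax_fold: 2.0           # observed ~twofold SHBG stimulation
      ec50: 0.34               # µmol/L unbound

carbamazepine:
  molecular_weight: 236.3
  pk: {ka_1_h: 0.5, v_l: 72.0, cl_l_h: 3.5, f_oral: 0.8, fu: 0.25}
  standard_doses_mg: [400, 600]
  interactions:
    - target: cyp3a4
      mechanism: induction
      emax_fold: 5.0
      ec50: 7.0                # µmol/L unbound

efavirenz:
  molecular_weight: 315.7
  pk: {ka_1_h: 0.6, v_l: 250.0, cl_l_h: 9.0, f_oral: 0.6, fu: 0.005}
  standard_doses_mg: [600]
  interactions:
    - target: cyp3a4
      mechanism: induction
      emax_fold: 7.4
      ec50: 0.06               # µmol/L unbound

itraconazole:
  # Parent compound only; the hydroxy-/keto-/N-desalkyl metabolite cascade
  # that contributes additional CYP3A4 inhibition in the full network model
  # is not represented (documented limitation).
  molecular_weight: 705.6
  pk: {ka_1_h: 0.5, v_l: 450.0, cl_l_h: 8.5, f_oral: 0.55, fu: 0.0036}
  standard_doses_mg: [100, 200]
  interactions:
    - target: cyp3a4
      mechanism: competitive
      ki: 0.0013               # µmol/L unbound

clarithromycin:
  molecular_weight: 748.0
  pk: {ka_1_h: 0.55, v_l: 191.0, cl_l_h: 12.7, f_oral: 0.55, fu: 0.30}
  standard_doses_mg: [250, 500]
  interactions:
    - target: cyp3a4
      mechanism: mbi
      kinact: 2.4              # 1/h
      ki_mbi: 9.3              # µmol/L (KI, half-maximal inactivation)
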