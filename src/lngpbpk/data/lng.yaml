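# Levonorgestrel (LNG) - victim compound, full PBPK treatment.
# Drug-specific parameters as published for the final LNG model (molecular
# weight, lipophilicity, binding kinetics, solubilities, clearances,
# permeabilities, dissolution).  Units are normalized internally to
# µmol/L, L, h unless stated.
name: LNG
molecular_weight: 312.4        # g/mol
lipophilicity_logp: 4.00
aqueous_solubility: 2.05       # mg/L
fassif_solubility: 14.0        # mg/L (pH 6.5); used for intestinal lumen
binding:
  - partner: albumin
    kd: 6.0                    # µmol/L
    koff: 6.50                 # 1/min
  - partner: shbg
    kd: 0.0005                 # µmol/L
    koff: 17.4                 # 1/min
cyp3a4_specific_clearance: 1.45   # µL/min/pmol CYP3A4, unbound-referenced
# Published value for the lumped non-CYP3A4 (phase II) hepatic pathway.  Its
# reference scale is platform-specific and is not used directly by the
# engine; the non-CYP3A4 intrinsic clearance is instead derived from the
# telithromycin-anchored CYP3A4 contribution below (see docs/methods.md).
other_hepatic_clearance: 0.10     # L/h/kg (stored verbatim)
# Fraction of LNG hepatic clearance mediated by CYP3A4 for the LNG-only
# product, back-calculated from the telithromycin DDI (AUCR 1.5 observed on
# the CHC, corrected for the 70% of the pathway available: 1.5/0.7 = 2.1).
fm_cyp3a4: 0.47
specific_intestinal_permeability: 0.0002  # cm/min
specific_organ_permeability: 0.31         # cm/min
formulations:
  - doses_mg: [0.03, 0.09, 0.15, 0.27]
    t80_dissolution_min: 30
    lag_time_min: 10
  - doses_mg: [0.75]
    t80_dissolution_min: 75
    lag_time_min: 0
  - doses_mg: [1.50]
    t80_dissolution_min: 180
    lag_time_min: 0
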