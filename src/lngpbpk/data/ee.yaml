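# Ethinyl estradiol (EE) - co-formulated estrogen, full PBPK treatment.
# EE does not bind SHBG; plasma binding is nonspecific with a constant
# unbound fraction.  "Protein binding: nonspecific 1.5%" is read as an
# unbound fraction of 1.5% (literature EE fu ~ 1.5-3% supports this
# reading; the bound-1.5% alternative would be physiologically
# implausible for a steroid).
# Intestinal permeability was published in cm/s and is normalized to
# cm/min here (1.0e-4 cm/s = 6.0e-3 cm/min).
name: EE
molecular_weight: 296.4        # g/mol
lipophilicity_logp: 3.6
aqueous_solubility: 3.9        # mg/L (3.9 µg/mL)
nonspecific_unbound_fraction: 0.015
total_hepatic_clearance: 4.1   # mL/min/kg body weight (plasma clearance)
specific_intestinal_permeability: 0.006   # cm/min (converted from 1.0e-4 cm/s)
specific_organ_permeability: 0.001        # cm/min
formulations:
  - doses_mg: [0.02, 0.03, 0.04, 0.05, 0.06]
    t80_dissolution_min: 40
    lag_time_min: 10
interactions:
  # Competitive CYP3A4 inhibition.  The published parameter set lists
  # Ki = 2 pmol/L while the accompanying text derives 10 pmol/L from the
  # calibration target of a 30% reduction in LNG fm_CYP3A4; the tabulated
  # value is the default here and can be overridden in scenario configs.
  - target: cyp3a4
    mechanism: competitive
    ki: 2.0e-06                # µmol/L (= 2 pmol/L)
  # SHBG synthesis stimulation, Emax on unbound EE.  Two alternative
  # parameterizations, selected by regimen type (mutually exclusive):
  # the net LNG:EE effect (~2.3-fold) when LNG is co-dosed, and the
  # EE-alone effect (2.25-fold).
  - target: shbg_synthesis
    mechanism: induction
    emax_fold: 2.3
    ec50: 1.0e-06              # µmol/L (= 1 pmol/L), unbound
    variant: net_lng_ee
  - target: shbg_synthesis
    mechanism: induction
    emax_fold: 2.25
    ec50: 1.0e-06
    variant: ee_alone
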