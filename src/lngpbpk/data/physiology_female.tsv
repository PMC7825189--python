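# Reference adult female physiology (ICRP-89-style reference woman, 60 kg, 163 cm).
# volume_l: organ volume; flow_frac: organ blood flow as fraction of cardiac output
# (lung receives the whole cardiac output in series and is excluded from the sum);
# density_kg_l: tissue density used for mass bookkeeping.
# Flow fractions are resting values; gut+spleen+liver(arterial) together form the
# hepatic inflow (portal convention handled in the engine).
organ	volume_l	flow_frac	density_kg_l
adipose	18.00	0.085	0.92
bone	7.80	0.050	1.30
brain	1.30	0.120	1.04
gut	1.10	0.160	1.04
heart	0.25	0.040	1.03
kidney	0.28	0.170	1.05
liver	1.40	0.065	1.06
lung	0.42	0.025	1.05
muscle	17.50	0.120	1.04
skin	2.30	0.050	1.10
spleen	0.13	0.020	1.06
rest	2.00	0.075	1.04
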