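# Fractional tissue composition for Rodgers-Rowland partition-coefficient
# calculation, transcribed from the Rodgers & Rowland tissue-composition
# tables (extracellular water, intracellular water, neutral lipid, neutral
# phospholipid volume fractions). The generic "rest" row is a muscle-like
# lumped remainder compartment.
organ	f_ew	f_iw	f_nl	f_np
adipose	0.135	0.010	0.8530	0.0016
bone	0.100	0.346	0.0273	0.0009
brain	0.162	0.620	0.0392	0.0533
gut	0.282	0.475	0.0292	0.0138
heart	0.320	0.456	0.0140	0.0118
kidney	0.273	0.483	0.0123	0.0284
liver	0.161	0.573	0.0135	0.0238
lung	0.336	0.446	0.0219	0.0148
muscle	0.118	0.630	0.0100	0.0090
skin	0.382	0.291	0.0239	0.0180
spleen	0.207	0.579	0.0077	0.0136
rest	0.300	0.450	0.0200	0.0100
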