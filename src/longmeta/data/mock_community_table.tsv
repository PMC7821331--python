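# Species composition of the two mock communities with the identity and
# reference alignment length of the best assignment per member. MC1 pooled
# DNA before amplification; MC2 amplified members separately then pooled.
# A dash marks a member not recovered in that community.
mc_id	species	group	percent_identity	alignment_length_bp
MC1	Aeshna cyanea	invertebrate	99.12	340
MC1	Baetis rhodani	invertebrate	99.34	603
MC1	Bufotes viridis	vertebrate	99.85	709
MC1	Caenis sp.	invertebrate	99.72	476
MC1	Chironomus salinarius	invertebrate	98.63	709
MC1	Cloeon dipterum	invertebrate	98.42	657
MC1	Esox lucius	vertebrate	99.43	572
MC1	Gammarus pulex	invertebrate	100.00	709
MC1	Iris pseudacorus	plant	100.00	1065
MC1	Lycopus europaeus	plant	100.00	981
MC1	Mentha spicata	plant	97.70	957
MC1	Mus musculus	vertebrate	99.84	682
MC1	Notonecta glauca	invertebrate	100.00	259
MC1	Nuphar lutea	plant	100.00	642
MC1	Nymphaea sp.	plant	99.38	161
MC1	Potamogeton perfoliatus	plant	100.00	495
MC1	Radix balthica	invertebrate	98.31	233
MC1	Tinca tinca	vertebrate	99.85	710
MC1	Utricularia australis	plant	99.23	967
MC2	Aeshna cyanea	invertebrate	98.74	440
MC2	Baetis rhodani	invertebrate	99.18	540
MC2	Bufotes viridis	vertebrate	99.84	709
MC2	Caenis sp.	invertebrate	100	285
MC2	Chironomus salinarius	invertebrate	98.69	306
MC2	Cloeon dipterum	invertebrate	100	667
MC2	Esox lucius	vertebrate	99.28	279
MC2	Gammarus pulex	invertebrate	100	520
MC2	Iris pseudacorus	plant	100	319
MC2	Lycopus europaeus	plant	100	669
MC2	Mentha spicata	plant	—	—
MC2	Mus musculus	vertebrate	99.31	436
MC2	Notonecta glauca	invertebrate	100	413
MC2	Nuphar lutea	plant	100	342
MC2	Nymphaea alba	plant	100	210
MC2	Potamogeton perfoliatus	plant	100	226
MC2	Radix balthica	invertebrate	97.6	242
MC2	Tinca tinca	vertebrate	99.8	519
MC2	Utricularia australis	plant	100	524
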