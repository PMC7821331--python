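# Captive feeding-trial regimes of six pond turtles (grams ingested per prey
# species) with the per-sample identity and reference alignment length
# recovered after de novo assembly. 16 detections over 6 samples.
sample_id	species	grams	percent_identity	alignment_length_bp
Emys_0	Esox lucius	20	98.52	323
Emys_0	Chironomus salinarius	5	97.84	573
Emys_1	Mus musculus	3	98.52	244
Emys_1	Chironomus salinarius	8	98.86	636
Emys_2	Esox lucius	19	97.83	366
Emys_2	Oncorhynchus mykiss	5	99.81	566
Emys_2	Mus musculus	6	99.77	567
Emys_2	Chironomus salinarius	5	98.71	588
Emys_2	Gammarus pulex	3	99.32	264
Emys_3	Esox lucius	10	99.78	566
Emys_3	Mus musculus	15	99.13	350
Emys_3	Chironomus salinarius	5	99.60	248
Emys_4	Chironomus salinarius	8	98.54	397
Emys_5	Esox lucius	13	100.00	499
Emys_5	Mus musculus	5	99.30	296
Emys_5	Gammarus pulex	3	100.00	275
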