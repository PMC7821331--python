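# 11-pair amplification panel: four COI pairs (animals) and seven plant pairs
# over matK, rbcL, 28S rRNA and trnL-trnF. Expected lengths are the average
# amplified fragment sizes observed with this panel.
marker_name	locus	target_group	direction	primer_name	sequence	expected_length_bp
COI-mlCOIint	COI	invertebrate	forward	mICOIintF	GGWACWGGWTGAACWGTWTAYCCYCC	350
COI-mlCOIint	COI	invertebrate	reverse	jgHCO2198	TAIACYTCIGGRTGICCRAARAAYCA	350
COI-ODO	COI	invertebrate	forward	ODO_LCO1490d	TTTCTACWAACCAYAAAGATATTGG	650
COI-ODO	COI	invertebrate	reverse	ODO_HCO2198d	TAAACTTCWGGRTGTCCAAARAATCA	650
COI-CO	COI	vertebrate	forward	COI-CO2	AYTCAACAAATCATAAAGATATTGG	600
COI-CO	COI	vertebrate	reverse	COI-CO4	ACYTCRGGRTGACCAAAAAATCA	600
COI-ModRep	COI	vertebrate	forward	Mod_RepCOI_F	TNTTYTCMACYAACCACAAAGA	650
COI-ModRep	COI	vertebrate	reverse	Mod_RepCOI_R	TTCDGGRTGNCCRAARAATCA	650
matK-KIM	matK	plant	forward	MatK-1RKIM-f	ACCCAGTCCATCTGGAAATCTTGGTTC	850
matK-KIM	matK	plant	reverse	MatK-3FKIM-r	CGTACAGTACTTTTGTGTTTACGAG	850
matK-472	matK	plant	forward	MatK-472-f	CCCRTYCATCTGGAAATCTTGGTTC	730
matK-472	matK	plant	reverse	MatK-1248-r	GCTRTRATAATGAGAAAGATTTCTGC	730
matK-5r	matK	plant	forward	MatK-5r	GTTCTAGCACAAGAAAGTCG	825
matK-5r	matK	plant	reverse	MatK-xf	TAATTTACGATCAATTCATTC	825
rbcL-a	rbcL	plant	forward	rbcL_a-F	ATGTCACCACAAACAGAGACTAAAGC	520
rbcL-a	rbcL	plant	reverse	rbcL_a-R	GTAAAATCAAGTCCACCRCG	520
rbcL-1F	rbcL	plant	forward	rbcL-1F	ATGTCACCACAAACAGAAAC	680
rbcL-1F	rbcL	plant	reverse	rbcL-724R	TCGCATGTACCTGCAGTAGC	680
28S	28S	plant	forward	28KJ	GGCGGTAAATTCCGTCC	630
28S	28S	plant	reverse	28C	GCTATCCTGAGGGAAACTTC	630
trnL-trnF	trnL-trnF	plant	forward	Tab_c	CGAAATCGGTAGACGCTACG	920
trnL-trnF	trnL-trnF	plant	reverse	Tab_f	ATTTGAACTGGTGACACGAG	920
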