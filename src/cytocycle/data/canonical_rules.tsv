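rule_id	marker	phases	expectation	threshold_mode	threshold_value
ki67_low_in_s	Ki67	S	high	quantile	0.10
cdt1_after_s	CDT1	G2+M	negative	quantile	0.60
prb_low_in_g2	pRbS780	G2	high	quantile	0.10
plk1_high_in_g0g1	PLK1	G0G1	low	quantile	0.90
slbp_high_after_s	SLBP	G2+M	low	quantile	0.50
geminin_high_in_g0g1	Geminin	G0G1	low	quantile	0.50
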