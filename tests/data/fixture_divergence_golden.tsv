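gene	hamming_vs_target_pct	mean_p_distance	nt_variability_pct	aa_variability_pct
NAD2	19.2	0.1722	29.3	56.3
COI	8.7	0.0911	16.5	35.5
12S	5.4	0.0547	10.4	
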