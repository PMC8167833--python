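sample_id	cnv_count_display	tumor_fraction
PC37	0	0.00
PC38	5+	0.62
PC39	5+	0.28
PC40	5+	0.12
PC41	5+	0.056
PC42	5+	0.32
PC43	5+	0.31
PC44	1	0.66
PC45	4	0.35
PC46	5+	0.26
PC47	0	0.00
PC48	5+	0.31
PC49	0	0.00
PC50	5+	0.61
PC51	0	0.00
PC52	5+	0.52
PC53	4	0.15
PC54	5+	0.11
PC55	2	0.31
PC56	0	0.00
PC57	0	0.00
PC58	5+	0.40
PC59	5+	0.55
PC60	5+	0.55
PC61	0	0.00
PC62	0	0.00
PC63	5+	0.96
PC64	0	0.00
PC65	0	0.00
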