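sample_id	bird_id	nest_of_origin	nest_of_rearing	age_class	nest_treatment	body_mass_g	tarsus_mm	replicate_id	sample_role
BN01_1_D8_r1	BN01_1	N01	N01	D8	crossfostered	11.57		r1	biological
BN01_1_D8_r2	BN01_1	N01	N01	D8	crossfostered	11.57		r2	biological
BN01_1_D15_r1	BN01_1	N01	N02	D15	crossfostered	18.72	19.2	r1	biological
BN01_1_D15_r2	BN01_1	N01	N02	D15	crossfostered	18.72	19.2	r2	biological
BN01_2_D8_r1	BN01_2	N01	N01	D8	crossfostered	12.35		r1	biological
BN01_2_D8_r2	BN01_2	N01	N01	D8	crossfostered	12.35		r2	biological
BN01_2_D15_r1	BN01_2	N01	N02	D15	crossfostered	18.42	19.59	r1	biological
BN01_2_D15_r2	BN01_2	N01	N02	D15	crossfostered	18.42	19.59	r2	biological
BN01_3_D8_r1	BN01_3	N01	N01	D8	crossfostered	11.78		r1	biological
BN01_3_D8_r2	BN01_3	N01	N01	D8	crossfostered	11.78		r2	biological
BN01_3_D15_r1	BN01_3	N01	N02	D15	crossfostered	18.42	19.37	r1	biological
BN01_3_D15_r2	BN01_3	N01	N02	D15	crossfostered	18.42	19.37	r2	biological
BN01_4_D8_r1	BN01_4	N01	N01	D8	crossfostered	12.2		r1	biological
BN01_4_D8_r2	BN01_4	N01	N01	D8	crossfostered	12.2		r2	biological
BN01_4_D15_r1	BN01_4	N01	N01	D15	crossfostered	18.93	19.72	r1	biological
BN01_4_D15_r2	BN01_4	N01	N01	D15	crossfostered	18.93	19.72	r2	biological
BN01_5_D8_r1	BN01_5	N01	N01	D8	crossfostered	10.54		r1	biological
BN01_5_D8_r2	BN01_5	N01	N01	D8	crossfostered	10.54		r2	biological
BN01_5_D15_r1	BN01_5	N01	N01	D15	crossfostered	16.34	18.46	r1	biological
BN01_5_D15_r2	BN01_5	N01	N01	D15	crossfostered	16.34	18.46	r2	biological
BN01_6_D8_r1	BN01_6	N01	N01	D8	crossfostered	12.53		r1	biological
BN01_6_D8_r2	BN01_6	N01	N01	D8	crossfostered	12.53		r2	biological
BN01_6_D15_r1	BN01_6	N01	N01	D15	crossfostered	19.1	20.18	r1	biological
BN01_6_D15_r2	BN01_6	N01	N01	D15	crossfostered	19.1	20.18	r2	biological
BN02_1_D8_r1	BN02_1	N02	N02	D8	crossfostered	17.79		r1	biological
BN02_1_D8_r2	BN02_1	N02	N02	D8	crossfostered	17.79		r2	biological
BN02_1_D15_r1	BN02_1	N02	N01	D15	crossfostered	17.77	19.38	r1	biological
BN02_1_D15_r2	BN02_1	N02	N01	D15	crossfostered	17.77	19.38	r2	biological
BN02_2_D8_r1	BN02_2	N02	N02	D8	crossfostered	12.07		r1	biological
BN02_2_D8_r2	BN02_2	N02	N02	D8	crossfostered	12.07		r2	biological
BN02_2_D15_r1	BN02_2	N02	N01	D15	crossfostered	18.68	19.2	r1	biological
BN02_2_D15_r2	BN02_2	N02	N01	D15	crossfostered	18.68	19.2	r2	biological
BN02_3_D8_r1	BN02_3	N02	N02	D8	crossfostered	11.49		r1	biological
BN02_3_D8_r2	BN02_3	N02	N02	D8	crossfostered	11.49		r2	biological
BN02_3_D15_r1	BN02_3	N02	N01	D15	crossfostered	17.19	18.77	r1	biological
BN02_3_D15_r2	BN02_3	N02	N01	D15	crossfostered	17.19	18.77	r2	biological
BN02_4_D8_r1	BN02_4	N02	N02	D8	crossfostered	11.79		r1	biological
BN02_4_D8_r2	BN02_4	N02	N02	D8	crossfostered	11.79		r2	biological
BN02_4_D15_r1	BN02_4	N02	N02	D15	crossfostered	17.36	19.07	r1	biological
BN02_4_D15_r2	BN02_4	N02	N02	D15	crossfostered	17.36	19.07	r2	biological
BN02_5_D8_r1	BN02_5	N02	N02	D8	crossfostered	11.45		r1	biological
BN02_5_D8_r2	BN02_5	N02	N02	D8	crossfostered	11.45		r2	biological
BN02_5_D15_r1	BN02_5	N02	N02	D15	crossfostered	17.39	18.47	r1	biological
BN02_5_D15_r2	BN02_5	N02	N02	D15	crossfostered	17.39	18.47	r2	biological
BN02_6_D8_r1	BN02_6	N02	N02	D8	crossfostered	13.22		r1	biological
BN02_6_D8_r2	BN02_6	N02	N02	D8	crossfostered	13.22		r2	biological
BN02_6_D15_r1	BN02_6	N02	N02	D15	crossfostered	19.8	20.14	r1	biological
BN02_6_D15_r2	BN02_6	N02	N02	D15	crossfostered	19.8	20.14	r2	biological
BN03_1_D8_r1	BN03_1	N03	N03	D8	control	11.11		r1	biological
BN03_1_D8_r2	BN03_1	N03	N03	D8	control	11.11		r2	biological
BN03_1_D15_r1	BN03_1	N03	N03	D15	control	16.8	18.84	r1	biological
BN03_1_D15_r2	BN03_1	N03	N03	D15	control	16.8	18.84	r2	biological
BN03_2_D8_r1	BN03_2	N03	N03	D8	control	11.3		r1	biological
BN03_2_D8_r2	BN03_2	N03	N03	D8	control	11.3		r2	biological
BN03_2_D15_r1	BN03_2	N03	N03	D15	control	17.05	18.63	r1	biological
BN03_2_D15_r2	BN03_2	N03	N03	D15	control	17.05	18.63	r2	biological
BN03_3_D8_r1	BN03_3	N03	N03	D8	control	12.08		r1	biological
BN03_3_D8_r2	BN03_3	N03	N03	D8	control	12.08		r2	biological
BN03_3_D15_r1	BN03_3	N03	N03	D15	control	17.37	19.3	r1	biological
BN03_3_D15_r2	BN03_3	N03	N03	D15	control	17.37	19.3	r2	biological
BN03_4_D8_r1	BN03_4	N03	N03	D8	control	10.93		r1	biological
BN03_4_D8_r2	BN03_4	N03	N03	D8	control	10.93		r2	biological
BN03_4_D15_r1	BN03_4	N03	N03	D15	control	16.39	18.48	r1	biological
BN03_4_D15_r2	BN03_4	N03	N03	D15	control	16.39	18.48	r2	biological
BN03_5_D8_r1	BN03_5	N03	N03	D8	control	11.34		r1	biological
BN03_5_D8_r2	BN03_5	N03	N03	D8	control	11.34		r2	biological
BN03_5_D15_r1	BN03_5	N03	N03	D15	control	16.51	18.7	r1	biological
BN03_5_D15_r2	BN03_5	N03	N03	D15	control	16.51	18.7	r2	biological
BN03_6_D8_r1	BN03_6	N03	N03	D8	control	12.22		r1	biological
BN03_6_D8_r2	BN03_6	N03	N03	D8	control	12.22		r2	biological
BN03_6_D15_r1	BN03_6	N03	N03	D15	control	18.68	19.57	r1	biological
BN03_6_D15_r2	BN03_6	N03	N03	D15	control	18.68	19.57	r2	biological
BN04_1_D8_r1	BN04_1	N04	N04	D8	control	12.65		r1	biological
BN04_1_D8_r2	BN04_1	N04	N04	D8	control	12.65		r2	biological
BN04_1_D15_r1	BN04_1	N04	N04	D15	control	18.58	19.59	r1	biological
BN04_1_D15_r2	BN04_1	N04	N04	D15	control	18.58	19.59	r2	biological
BN04_2_D8_r1	BN04_2	N04	N04	D8	control	12.34		r1	biological
BN04_2_D8_r2	BN04_2	N04	N04	D8	control	12.34		r2	biological
BN04_2_D15_r1	BN04_2	N04	N04	D15	control	18.88	19.97	r1	biological
BN04_2_D15_r2	BN04_2	N04	N04	D15	control	18.88	19.97	r2	biological
BN04_3_D8_r1	BN04_3	N04	N04	D8	control	12.52		r1	biological
BN04_3_D8_r2	BN04_3	N04	N04	D8	control	12.52		r2	biological
BN04_3_D15_r1	BN04_3	N04	N04	D15	control	18.9	19.49	r1	biological
BN04_3_D15_r2	BN04_3	N04	N04	D15	control	18.9	19.49	r2	biological
BN04_4_D8_r1	BN04_4	N04	N04	D8	control	11.55		r1	biological
BN04_4_D8_r2	BN04_4	N04	N04	D8	control	11.55		r2	biological
BN04_4_D15_r1	BN04_4	N04	N04	D15	control	17.1	18.88	r1	biological
BN04_4_D15_r2	BN04_4	N04	N04	D15	control	17.1	18.88	r2	biological
BN04_5_D8_r1	BN04_5	N04	N04	D8	control	10.87		r1	biological
BN04_5_D8_r2	BN04_5	N04	N04	D8	control	10.87		r2	biological
BN04_5_D15_r1	BN04_5	N04	N04	D15	control	16.73	18.48	r1	biological
BN04_5_D15_r2	BN04_5	N04	N04	D15	control	16.73	18.48	r2	biological
BN04_6_D8_r1	BN04_6	N04	N04	D8	control	13.02		r1	biological
BN04_6_D8_r2	BN04_6	N04	N04	D8	control	13.02		r2	biological
BN04_6_D15_r1	BN04_6	N04	N04	D15	control	19.35	19.96	r1	biological
BN04_6_D15_r2	BN04_6	N04	N04	D15	control	19.35	19.96	r2	biological
BLANK_01								r1	blank
BLANK_02								r1	blank
BLANK_03								r1	blank
BLANK_04								r1	blank
NEG_01								r1	negative_control
NEG_02								r1	negative_control
NEG_03								r1	negative_control
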