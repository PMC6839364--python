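organ_id	beta_m	beta_f	gamma	eta	source
lung	2.3	3.4	-0.41	5.2	specific
stomach	7.0	7.1	0.002	1.8	specific
esophagus	5.1	4.2	-0.39	1.9	other_solid
liver	2.2	1.0	-0.41	4.1	specific
thyroid	5.1	4.2	-0.39	1.9	other_solid
skin	5.1	4.2	-0.39	1.9	other_solid
intestine	2.2	0.84	-1.00	5.7	specific
kidney	5.1	4.2	-0.39	1.9	other_solid
pancreas	5.1	4.2	-0.39	1.9	other_solid
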