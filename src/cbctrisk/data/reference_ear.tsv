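organ_id	cohort	mode	ear_male	ear_female
lung	lung	thorax	3.9	5.8
lung	lung	pelvis	15.7	23.1
lung	lung	fourd	7.3	10.8
lung	liver	thorax	2.1	3.2
lung	liver	pelvis	8.5	12.6
lung	liver	fourd	4.0	5.9
stomach	lung	thorax	3.3	3.3
stomach	lung	pelvis	13.2	13.4
stomach	lung	fourd	6.2	6.2
stomach	liver	thorax	8.9	9.0
stomach	liver	pelvis	35.7	36.2
stomach	liver	fourd	16.7	16.9
esophagus	lung	thorax	5.1	4.2
esophagus	lung	pelvis	20.4	16.8
esophagus	lung	fourd	9.6	7.9
esophagus	liver	thorax	3.2	2.7
esophagus	liver	pelvis	12.9	10.7
esophagus	liver	fourd	6.0	5.0
liver	lung	thorax	2.0	0.9
liver	lung	pelvis	8.1	3.7
liver	lung	fourd	3.8	1.7
liver	liver	thorax	5.3	2.4
liver	liver	pelvis	21.2	9.6
liver	liver	fourd	9.9	4.5
thyroid	lung	thorax	6.9	5.7
thyroid	lung	pelvis	27.5	22.7
thyroid	lung	fourd	12.9	10.6
skin	lung	thorax	3.0	2.5
skin	lung	pelvis	12.0	9.9
skin	lung	fourd	5.6	4.6
skin	liver	thorax	3.6	2.9
skin	liver	pelvis	14.3	11.8
skin	liver	fourd	6.7	5.5
intestine	lung	thorax	0.8	0.3
intestine	lung	pelvis	3.1	1.2
intestine	lung	fourd	1.4	0.6
intestine	liver	thorax	3.1	1.2
intestine	liver	pelvis	12.3	4.7
intestine	liver	fourd	5.7	2.2
kidney	lung	thorax	0.9	0.8
kidney	lung	pelvis	3.7	3.0
kidney	lung	fourd	1.7	1.4
kidney	liver	thorax	6.9	5.7
kidney	liver	pelvis	27.7	22.8
kidney	liver	fourd	12.9	10.7
pancreas	lung	thorax	1.5	1.3
pancreas	lung	pelvis	6.2	5.1
pancreas	lung	fourd	2.9	2.4
pancreas	liver	thorax	9.2	7.6
pancreas	liver	pelvis	37.0	30.4
pancreas	liver	fourd	17.3	14.2
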