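cohort	mode	effective_dose_mSv	sd_mSv
lung	thorax	3.9	0.5
lung	pelvis	15.7	2.0
lung	fourd	7.3	0.9
liver	thorax	4.2	0.6
liver	pelvis	16.7	2.4
liver	fourd	7.8	1.1
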