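organ_id	cohort	mode	mean_dose_mGy	sd_mGy	volume_cm3	volume_sd_cm3
lung	lung	thorax	7.6	1.2	2259.0	722.5
lung	lung	pelvis	30.5	4.6	2259.0	722.5
lung	lung	fourd	14.3	2.2	2259.0	722.5
lung	liver	thorax	4.2	0.9	2259.0	722.5
lung	liver	pelvis	16.7	3.6	2259.0	722.5
lung	liver	fourd	7.8	1.7	2259.0	722.5
stomach	lung	thorax	3.6	2.1	229.4	175.7
stomach	lung	pelvis	14.3	8.2	229.4	175.7
stomach	lung	fourd	6.7	3.8	229.4	175.7
stomach	liver	thorax	9.6	2.6	229.4	175.7
stomach	liver	pelvis	38.6	10.3	229.4	175.7
stomach	liver	fourd	18.0	4.8	229.4	175.7
bone_marrow	lung	thorax	10.8	2.2	324.6	118.1
bone_marrow	lung	pelvis	43.1	8.7	324.6	118.1
bone_marrow	lung	fourd	20.2	4.1	324.6	118.1
bone_marrow	liver	thorax	8.1	3.3	324.6	118.1
bone_marrow	liver	pelvis	32.4	13.4	324.6	118.1
bone_marrow	liver	fourd	15.1	6.2	324.6	118.1
esophagus	lung	thorax	7.5	1.8	33.7	13.1
esophagus	lung	pelvis	29.9	7.2	33.7	13.1
esophagus	lung	fourd	14.0	3.3	33.7	13.1
esophagus	liver	thorax	4.7	0.9	33.7	13.1
esophagus	liver	pelvis	18.9	3.8	33.7	13.1
esophagus	liver	fourd	8.8	1.8	33.7	13.1
liver	lung	thorax	4.9	2.3	1049.4	218.9
liver	lung	pelvis	19.6	9.3	1049.4	218.9
liver	lung	fourd	9.1	4.4	1049.4	218.9
liver	liver	thorax	12.8	3.0	1049.4	218.9
liver	liver	pelvis	51.3	12.1	1049.4	218.9
liver	liver	fourd	24.0	5.6	1049.4	218.9
thyroid	lung	thorax	10.1	10.8	18.4	15.5
thyroid	lung	pelvis	40.2	43.2	18.4	15.5
thyroid	lung	fourd	18.8	20.2	18.4	15.5
bone_surface	lung	thorax	12.7	2.2	990.5	321.0
bone_surface	lung	pelvis	51.0	8.6	990.5	321.0
bone_surface	lung	fourd	23.8	4.0	990.5	321.0
bone_surface	liver	thorax	10.7	2.5	990.5	321.0
bone_surface	liver	pelvis	42.8	10.0	990.5	321.0
bone_surface	liver	fourd	20.0	4.7	990.5	321.0
skin	lung	thorax	4.4	0.6	931.4	179.5
skin	lung	pelvis	17.6	2.6	931.4	179.5
skin	lung	fourd	8.2	1.2	931.4	179.5
skin	liver	thorax	5.2	1.2	931.4	179.5
skin	liver	pelvis	20.9	4.8	931.4	179.5
skin	liver	fourd	9.8	2.2	931.4	179.5
adrenal_glands	lung	thorax	2.8	2.1	3.0	1.6
adrenal_glands	lung	pelvis	11.2	8.5	3.0	1.6
adrenal_glands	lung	fourd	5.2	4.0	3.0	1.6
adrenal_glands	liver	thorax	8.7	2.3	3.0	1.6
adrenal_glands	liver	pelvis	34.8	9.0	3.0	1.6
adrenal_glands	liver	fourd	16.3	4.2	3.0	1.6
gallbladder	lung	thorax	2.2	2.0	12.7	13.1
gallbladder	lung	pelvis	8.8	7.9	12.7	13.1
gallbladder	lung	fourd	4.1	3.7	12.7	13.1
gallbladder	liver	thorax	8.6	3.9	12.7	13.1
gallbladder	liver	pelvis	34.3	15.6	12.7	13.1
gallbladder	liver	fourd	16.0	7.3	12.7	13.1
heart	lung	thorax	8.5	2.1	712.3	263.5
heart	lung	pelvis	34.2	8.2	712.3	263.5
heart	lung	fourd	16.0	3.8	712.3	263.5
heart	liver	thorax	13.1	3.1	712.3	263.5
heart	liver	pelvis	52.3	12.3	712.3	263.5
heart	liver	fourd	24.5	5.8	712.3	263.5
intestine	lung	thorax	1.5	0.8	556.0	262.7
intestine	lung	pelvis	5.9	3.2	556.0	262.7
intestine	lung	fourd	2.7	1.5	556.0	262.7
intestine	liver	thorax	5.8	2.1	556.0	262.7
intestine	liver	pelvis	23.2	8.3	556.0	262.7
intestine	liver	fourd	10.8	3.9	556.0	262.7
kidney	lung	thorax	1.3	1.1	251.9	79.6
kidney	lung	pelvis	5.4	4.5	251.9	79.6
kidney	lung	fourd	2.5	2.1	251.9	79.6
kidney	liver	thorax	10.1	3.4	251.9	79.6
kidney	liver	pelvis	40.5	13.7	251.9	79.6
kidney	liver	fourd	18.9	6.4	251.9	79.6
pancreas	lung	thorax	2.3	1.8	32.1	14.1
pancreas	lung	pelvis	9.1	7.2	32.1	14.1
pancreas	lung	fourd	4.2	3.4	32.1	14.1
pancreas	liver	thorax	13.5	3.5	32.1	14.1
pancreas	liver	pelvis	54.1	14.0	32.1	14.1
pancreas	liver	fourd	25.3	6.5	32.1	14.1
spleen	lung	thorax	4.4	3.0	129.5	85.8
spleen	lung	pelvis	17.6	11.9	129.5	85.8
spleen	lung	fourd	8.2	5.6	129.5	85.8
spleen	liver	thorax	14.9	2.9	129.5	85.8
spleen	liver	pelvis	59.5	11.6	129.5	85.8
spleen	liver	fourd	27.8	5.4	129.5	85.8
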