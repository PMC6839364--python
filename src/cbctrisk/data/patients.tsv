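cohort	patient	sex	height_cm	weight_kg	bmi	tumor_location
lung	1	F	147.3	49.2	22.7	RUL
lung	2	M	157.0	45.6	18.5	RML
lung	3	F	156.2	51.1	20.9	LLL
lung	4	M	164.0	49.0	18.2	RML
lung	5	F	138.6	31.4	16.3	RLL
lung	6	M	158.6	55.3	22.0	RUL
lung	7	F	137.0	40.6	21.6	RLL
lung	8	F	146.0	55.0	25.8	RLL
lung	9	M				LLL
lung	10	M	158.5	63.3	25.2	RUL
lung	11	M	169.3	48.3	16.9	LLL
lung	12	M	166.0	69.6	25.3	RLL
lung	13	F	147.8	51.5	23.6	LUL
lung	14	F	150.7	48.9	21.5	RLL
lung	15	F	166.8	69.0	24.8	LLL
liver	1	M	156.0	55.7	22.9	S4
liver	2	F	146.7	49.2	22.9	S1
liver	3	F	145.3	46.4	22.0	S8
liver	4	M	159.2	54.0	21.3	S5
liver	5	M	166.2	63.1	22.8	PVTT
liver	6	M	159.5	49.2	19.3	S3
liver	7	M	159.2	50.5	19.9	S4,S7
liver	8	M	168.8	49.5	17.4	S7
liver	9	M	162.7	46.9	17.7	S3,S4
liver	10	M	168.5	59.1	20.8	PVTT
liver	11	M	155.9	64.0	26.3	S8
liver	12	F	146.3	68.6	32.1	S2
liver	13	M	162.4	53.0	20.1	S2
liver	14	M	165.7	86.4	31.5	S7
liver	15	M	162.1	52.8	20.1	PVTT
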