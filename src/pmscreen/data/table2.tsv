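accession	name	art1_ratio	art1_flag	art2_ratio	art2_flag	art3_ratio	art3_flag	art4_ratio	art4_flag	art5_ratio	art5_flag	art6_ratio	art6_flag	art7_ratio	art7_flag	art8_ratio	art8_flag	art9_ratio	art9_flag	art10_ratio	art10_flag	bul1_ratio	bul1_flag	bul2_ratio	bul2_flag
P32901	PTR2	9.0	none	10.8	none	10.8	none	6.2	none	11.2	none	8.6	none	2.6	none	4.4	none	2.6	none	2.3	none	17.7	up	2.4	none
Q05998	THI7	1.2	none	4.1	up	1.0	none	0.6	none	0.8	none	0.4	none	0.3	none	0.3	none	11.3	up	0.3	none	0.5	none	0.3	none
P38631	FKS1	5.2	none	3.0	none	5.5	none	2.5	none	3.2	none	2.1	none	1.7	none	1.4	none	3.5	none	1.8	none	2.9	none	1.0	none
P04817	CAN1	3.5	up	2.0	none	1.4	none	1.4	none	1.2	none	1.4	none	1.5	none	1.7	none	6.5	none	1.2	none	1.2	none	1.8	none
Q01896	ENA2	1.7	none	2.4	none	6.8	none	4.7	none	1.5	none	1.1	none	1.5	none	1.4	none	1.7	none	1.4	none	0.5	none	1.1	none
P32791	FRE1	5.4	none	4.2	none	4.7	none	3.1	none	3.6	none	2.4	none	2.5	none	1.9	none	2.8	none	1.9	none	2.8	none	1.7	none
P32466	HXT3	3.0	none	1.5	none	2.1	none	8.4	up	1.3	none	0.7	none	1.7	none	0.8	none	3.6	none	1.2	none	1.5	none	0.7	none
P38085	TAT1	2.4	none	1.8	none	2.2	none	1.1	none	1.6	none	1.6	none	1.4	none	1.4	none	0.7	none	1.2	none	1.2	none	1.6	none
Q06689	INA1	1.2	none	0.9	none	1.6	none	0.8	none	0.8	none	0.4	none	0.8	none	0.4	none	0.5	none	0.7	none	0.1	none	0.3	none
P32465	HXT1	4.6	none	2.8	none	4.4	none	9.3	up	2.6	none	1.6	none	2.2	none	1.8	none	1.7	none	2.4	none	1.4	none	1.9	none
P39004	HXT7	0.6	none	0.4	none	0.3	none	1.1	none	0.6	none	0.2	none	0.9	none	0.6	none	0.1	none	0.7	none	0.1	none	0.4	none
P32467	HXT4	0.7	none	0.6	none	0.6	none	2.8	none	0.5	none	0.6	none	0.7	none	0.5	none	0.4	none	0.6	none	0.2	none	0.5	none
P38079	YRO2	3.9	none	1.2	none	2.8	none	1.2	none	1.5	none	0.6	none	2.0	none	1.1	none	0.4	none	1.5	none	1.7	none	0.5	none
P40088	FTR1	2.2	none	1.0	none	1.8	none	1.6	none	1.7	none	0.8	none	1.3	none	0.6	none	2.1	none	1.1	none	1.2	none	0.5	none
P05030	PMA1	4.8	none	0.7	none	2.9	none	1.6	none	2.2	none	0.5	none	1.3	none	0.4	none	0.4	none	0.8	none	0.6	none	0.3	none
Q12256	TPO4	3.2	none	1.5	none	2.1	none	2.1	none	1.8	none	1.4	none	1.6	none	1.0	none	0.2	none	1.1	none	0.8	none	1.0	none
P38993	FET3	2.8	none	0.8	none	1.4	none	1.7	none	1.8	none	1.1	none	1.2	none	0.6	none	2.1	none	0.9	none	1.1	none	0.7	none
P49573	CTR1	1.2	none	1.3	none	2.0	none	1.5	none	1.3	none	1.1	none	1.4	none	0.9	none	0.4	none	1.1	none	1.1	none	0.8	none
P40474	QDR2	0.7	none	0.7	none	1.0	none	0.7	none	0.6	none	0.4	none	1.0	none	0.7	none	1.2	none	0.9	none	0.3	none	0.4	none
P22146	GAS1	1.7	none	1.2	none	2.0	none	1.0	none	1.1	none	0.3	none	1.4	none	0.7	none	0.2	down	1.1	none	0.7	none	0.3	down
P33302	PDR5	0.8	none	2.4	none	4.7	none	2.9	none	2.4	none	1.1	none	3.0	none	1.4	none	2.1	none	2.2	none	0.5	none	1.4	none
P32568	SNQ2	1.9	none	1.5	none	2.6	none	1.3	none	1.3	none	0.8	none	2.4	none	1.1	none	2.6	none	1.5	none	1.4	none	0.7	none
P53049	YOR1	2.3	none	1.5	none	1.8	none	1.5	none	1.7	none	0.8	none	1.5	none	1.1	none	1.4	none	1.1	none	1.1	none	0.7	none
P23292	YCK2	1.4	none	0.8	none	1.3	none	1.2	none	1.1	none	0.7	none	1.1	none	0.8	none	0.9	none	0.9	none	0.8	none	0.7	none
P48231	TCB2	0.4	none	0.8	none	0.7	none	0.8	none	0.5	none	0.5	none	0.7	none	0.7	none	1.1	none	0.8	none	0.7	none	0.5	none
P01120	RAS2	1.1	none	0.8	none	1.3	none	1.0	none	1.1	none	0.7	none	1.0	none	0.6	none	0.1	down	0.9	none	0.7	none	0.5	down
Q12466	TCB1	0.4	none	0.4	none	0.5	none	0.7	none	0.5	none	0.3	none	0.7	none	0.6	none	0.6	none	0.7	none	0.4	none	0.3	none
Q00245	RHO3	1.0	none	0.9	none	1.0	none	1.0	none	1.0	none	0.5	none	0.9	none	0.7	none	1.1	none	0.7	none	0.4	none	0.5	none
Q03640	TCB3	0.4	none	0.5	none	0.7	none	0.7	none	0.5	none	0.3	none	0.6	none	0.5	none	0.8	none	0.6	none	0.4	none	0.3	none
P38250	IST2	0.5	none	0.4	none	0.6	none	0.8	none	0.6	none	0.5	none	0.6	none	0.5	none	1.1	none	0.9	none	0.6	none	0.3	none
Q12207	NCE102	0.8	none	0.5	none	0.8	none	0.4	none	0.6	none	0.4	none	0.8	none	0.7	none	0.3	none	0.8	none	0.5	none	0.4	none
P06780	RHO1	0.7	none	0.6	none	0.8	none	0.6	none	0.8	none	0.5	none	0.8	none	0.7	none	0.5	none	0.7	none	0.8	none	0.4	none
Q08245	ZEO1	0.6	none	0.9	none	1.3	none	0.4	none	0.9	none	0.4	none	1.1	none	0.9	none	0.2	none	0.9	none	0.5	none	0.4	none
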