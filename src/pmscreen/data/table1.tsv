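accession	name	ratio_chx_vs_ctrl	flag
P32901	PTR2	0.03	down
Q05998	THI7	0.14	down
P38631	FKS1	0.18	down
P04817	CAN1	0.19	down
Q01896	ENA2	0.24	down
P32791	FRE1	0.31	down
P32466	HXT3	0.35	down
P38085	TAT1	0.38	down
Q06689	INA1	0.41	down
P32465	HXT1	0.42	down
P39004	HXT7	0.44	down
P32467	HXT4	0.48	down
P38079	YRO2	0.55	down
P40088	FTR1	0.55	down
P05030	PMA1	0.58	down
Q12256	TPO4	0.58	down
P38993	FET3	0.60	down
P49573	CTR1	0.63	down
P40474	QDR2	0.64	down
P22146	GAS1	0.74	down
P33302	PDR5	0.84	down
P32568	SNQ2	0.85	down
P53049	YOR1	0.87	down
P23292	YCK2	0.88	down
P48231	TCB2	1.50	up
P01120	RAS2	1.55	up
Q12466	TCB1	1.88	up
Q00245	RHO3	1.95	up
Q03640	TCB3	2.05	up
P38250	IST2	2.74	up
Q12207	NCE102	3.16	up
P06780	RHO1	3.81	up
Q08245	ZEO1	16.42	up
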