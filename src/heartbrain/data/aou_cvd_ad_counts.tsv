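subtype	cvd_status	n	printed_pct	n_without_ad	printed_pct_without	n_with_ad	printed_pct_with
hypertension	No	182015	63.4	181840	99.9	175	0.1
hypertension	Yes	104996	36.6	104397	99.4	599	0.6
hypotension	No	269538	93.9	268956	99.8	582	0.2
hypotension	Yes	17473	6.1	17281	98.9	192	1.1
angina_pectoris	No	278021	96.9	277322	99.7	699	0.3
angina_pectoris	Yes	8990	3.1	8915	99.2	75	0.8
acute_myocardial_infarction	No	280431	97.7	279711	99.7	720	0.3
acute_myocardial_infarction	Yes	6580	2.3	6526	99.2	54	0.8
atrial_fibrillation	No	270197	94.1	269607	99.8	590	0.2
atrial_fibrillation	Yes	16814	5.9	16630	98.9	184	1.1
heart_failure	No	268407	93.5	267828	99.8	579	0.2
heart_failure	Yes	18604	6.5	18409	99.0	195	1.0
blockage	No	278876	97.2	278201	99.8	675	0.2
blockage	Yes	8135	2.8	8036	98.8	99	1.2
chronic_rheumatic_heart_disease	No	278976	97.2	278277	99.7	699	0.3
chronic_rheumatic_heart_disease	Yes	8035	2.8	7960	99.1	75	0.9
chronic_ischemic_heart_disease	No	254852	88.8	254401	99.8	451	0.2
chronic_ischemic_heart_disease	Yes	32159	11.2	31836	99.0	323	1.0
cerebral_infarction	No	279084	97.2	278417	99.8	667	0.2
cerebral_infarction	Yes	7927	2.8	7820	98.7	107	1.3
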