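subtype	cvd_status	n	printed_pct	n_without_ad	printed_pct_without	n_with_ad	printed_pct_with
hypertension	No	339872	67.7	338205	99.5	1667	0.5
hypertension	Yes	162261	32.3	159799	98.5	2462	1.5
hypotension	No	480823	95.8	477440	99.3	3383	0.7
hypotension	Yes	21310	4.2	20564	96.5	746	3.5
angina_pectoris	No	467966	93.2	464473	99.3	3493	0.7
angina_pectoris	Yes	34167	6.8	33531	98.1	636	1.9
acute_myocardial_infarction	No	484311	96.5	480433	99.2	3878	0.8
acute_myocardial_infarction	Yes	17822	3.5	17571	98.6	251	1.4
pulmonary_embolism	No	492066	98.0	488111	99.2	3955	0.8
pulmonary_embolism	Yes	10067	2.0	9893	98.3	174	1.7
atrial_fibrillation	No	460772	91.8	457474	99.3	3298	0.7
atrial_fibrillation	Yes	41361	8.2	40530	98.0	831	2.0
heart_failure	No	482058	96.0	478397	99.2	3661	0.8
heart_failure	Yes	20075	4.0	19607	97.7	468	2.3
blockage	No	488114	97.2	484345	99.2	3769	0.8
blockage	Yes	14019	2.8	13659	97.4	360	2.6
chronic_rheumatic_heart_disease	No	490849	97.8	486930	99.2	3919	0.8
chronic_rheumatic_heart_disease	Yes	11284	2.2	11074	98.1	210	1.9
chronic_ischemic_heart_disease	No	448703	89.4	445508	99.3	3195	0.7
chronic_ischemic_heart_disease	Yes	53430	10.6	52496	98.3	934	1.7
cerebral_infarction	No	491788	97.9	487900	99.2	3888	0.8
cerebral_infarction	Yes	10345	2.1	10104	97.7	241	2.3
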