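covariate	level	n_full	printed_pct_full	n_without_ad	printed_pct_without	n_with_ad	printed_pct_with
Diabetes	No	457702	91.2	454399	91.2	3303	80.0
Diabetes	Yes	44431	8.8	43605	8.8	826	20.0
Sex	Female	273158	54.4	271004	54.4	2154	52.2
Sex	Male	228975	45.6	227000	45.6	1975	47.8
Age completed full time education	NA	165587	33.0	164722	33.1	865	20.9
BMI	NA	3103	0.6	3063	0.6	40	1.0
Smoking Status	Never	273328	54.4	271336	54.5	1992	48.2
Smoking Status	Previous	172920	34.4	171206	34.4	1714	41.5
Smoking Status	Current	52937	10.5	52566	10.6	371	9.0
Smoking Status	Prefer not to answer	2948	0.6	2896	0.6	52	1.3
Depression/Bipolar Disorder	No	468716	93.3	464772	93.3	3944	95.5
Depression/Bipolar Disorder	Yes	33417	6.7	33232	6.7	185	4.5
Days of moderate physical activity each week	NA	27251	5.4	26876	5.4	375	9.1
Days of vigorous physical activity each week	NA	27565	5.5	27157	5.5	408	9.9
Alcohol Consumption	Daily or almost daily	603	0.1	595	0.1	8	0.2
Alcohol Consumption	3-4 times a week	101716	20.3	100933	20.3	783	19.0
Alcohol Consumption	1-2 times a week	115357	23.0	114552	23.0	805	19.5
Alcohol Consumption	1-3 times a month	129186	25.7	128215	25.7	971	23.5
Alcohol Consumption	Special occasions only	55811	11.1	55392	11.1	419	10.1
Alcohol Consumption	Never	57967	11.5	57379	11.5	588	14.2
Alcohol Consumption	Prefer not to answer	41493	8.3	40938	8.2	555	13.4
Annual Household Income	<18000	49778	9.9	49203	9.9	575	13.9
Annual Household Income	18000-30999	21295	4.2	20900	4.2	395	9.6
Annual Household Income	31000-51999	97143	19.3	95768	19.2	1375	33.3
Annual Household Income	52000-100000	108101	21.5	107135	21.5	966	23.4
Annual Household Income	>100000	110690	22.0	110226	22.1	464	11.2
Annual Household Income	Do not know	86204	17.2	86009	17.3	195	4.7
Annual Household Income	Prefer not to answer	28922	5.8	28763	5.8	159	3.9
Ethnic background	White	472365	94.1	468415	94.1	3950	95.7
Ethnic background	Black	8048	1.6	7990	1.6	58	1.4
Ethnic background	Asian	9872	2.0	9818	2.0	54	1.3
Ethnic background	Chinese	1571	0.3	1567	0.3	4	0.1
Ethnic background	Mixed	2950	0.6	2937	0.6	13	0.3
Ethnic background	Other	4552	0.9	4529	0.9	23	0.6
Ethnic background	Unknown	217	0.0	216	0.0	1	0.0
Ethnic background	Prefer not to answer	2558	0.5	2532	0.5	26	0.6
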