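covariate	level	n_full	printed_pct_full	n_without_ad	printed_pct_without	n_with_ad	printed_pct_with
Diabetes	No	237281	82.7	236807	82.7	474	61.2
Diabetes	Yes	49730	17.3	49430	17.3	300	38.8
Sex	Female	172401	60.1	171999	60.1	402	51.9
Sex	Male	108739	37.9	108388	37.9	351	45.3
Sex	Intersex	57	0.0	57	0.0	0	0.0
Sex	No matching concept	2702	0.9	2692	0.9	10	1.3
Sex	None	96	0.0	96	0.0	0	0.0
Sex	Prefer not to answer	3016	1.1	3005	1.0	11	1.4
Highest Level of Education	Never Attended	421	0.1	416	0.1	5	0.6
Highest Level of Education	Grades 1-4	2548	0.9	2532	0.9	16	2.1
Highest Level of Education	Grades 5-8	6745	2.4	6700	2.3	45	5.8
Highest Level of Education	Grades 9-11	18153	6.3	18115	6.3	38	4.9
Highest Level of Education	Grade 12 Or GED	56778	19.8	56647	19.8	131	16.9
Highest Level of Education	1-3 Years College	72938	25.4	72780	25.4	158	20.4
Highest Level of Education	College Graduate	62550	21.8	62394	21.8	156	20.2
Highest Level of Education	Advanced Degree	57696	20.1	57494	20.1	202	26.1
Highest Level of Education	Prefer not to answer	9182	3.2	9159	3.2	23	3.0
BMI	NA	12715	4.4	12676	4.4	39	5.0
Smoked 100 Cigarettes in Lifetime	No	164021	57.1	163612	57.2	409	52.8
Smoked 100 Cigarettes in Lifetime	Yes	114595	39.9	114253	39.9	342	44.2
Smoked 100 Cigarettes in Lifetime	Don't Know	3645	1.3	3636	1.3	9	1.2
Smoked 100 Cigarettes in Lifetime	Prefer not to answer	4750	1.7	4736	1.7	14	1.8
Depression	No	208532	72.7	208193	72.7	339	43.8
Depression	Yes	78479	27.3	78044	27.3	435	56.2
Frequency of Alcoholic Drinks over Past Year	4 or More Per Week	30087	10.5	30003	10.5	84	10.9
Frequency of Alcoholic Drinks over Past Year	2 to 3 Per Week	34981	12.2	34920	12.2	61	7.9
Frequency of Alcoholic Drinks over Past Year	2 to 4 Per Month	52212	18.2	52117	18.2	95	12.3
Frequency of Alcoholic Drinks over Past Year	Monthly Or Less	84407	29.4	84226	29.4	181	23.4
Frequency of Alcoholic Drinks over Past Year	Never	46653	16.3	46422	16.2	231	29.8
Frequency of Alcoholic Drinks over Past Year	Prefer not to answer	38671	13.5	38549	13.5	122	15.8
Annual Household Income	<10000	40856	14.2	40781	14.2	75	9.7
Annual Household Income	10000-25000	33965	11.8	33851	11.8	114	14.7
Annual Household Income	25000-35000	20267	7.1	20216	7.1	51	6.6
Annual Household Income	35000-50000	22252	7.8	22184	7.8	68	8.8
Annual Household Income	50000-75000	29186	10.2	29106	10.2	80	10.3
Annual Household Income	75000-100000	22359	7.8	22308	7.8	51	6.6
Annual Household Income	100000-150000	27202	9.5	27146	9.5	56	7.2
Annual Household Income	150000-200000	12496	4.4	12472	4.4	24	3.1
Annual Household Income	>200000	17507	6.1	17480	6.1	27	3.5
Annual Household Income	Prefer not to answer	60921	21.2	60693	21.2	228	29.5
Ethnicity	White	150402	52.4	149897	52.4	505	65.2
Ethnicity	Black	57177	19.9	57088	19.9	89	11.5
Ethnicity	Hispanic	47699	16.6	47579	16.6	120	15.5
Ethnicity	Asian	8038	2.8	8025	2.8	13	1.7
Ethnicity	MENA	1605	0.6	1603	0.6	2	0.3
Ethnicity	NHPI	297	0.1	296	0.1	1	0.1
Ethnicity	Mixed	10771	3.8	10755	3.8	16	2.1
Ethnicity	None Of These	3017	1.1	3017	1.1	0	0.0
Ethnicity	Prefer not to answer	8005	2.8	7977	2.8	28	3.6
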