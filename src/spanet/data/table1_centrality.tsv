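province	in_degree	out_degree	degree	betweenness	closeness
Beijing	11	4	36.667	0.807	57.692
Tianjin	8	3	26.667	0.230	53.571
Hebei	14	5	46.667	1.943	61.224
Shanxi	7	7	33.333	0.690	60.000
Inner Mongolia	0	7	23.333	0.272	56.604
Liaoning	2	8	30.000	0.706	58.824
Jilin	2	8	26.667	0.272	57.692
Heilongjiang	1	9	30.000	0.706	58.824
Shanghai	4	3	13.333	0.000	50.847
Jiangsu	27	6	90.000	17.409	90.909
Zhejiang	12	3	40.000	1.825	62.500
Anhui	12	7	40.000	0.915	62.500
Fujian	3	10	33.333	0.497	60.000
Jiangxi	5	9	30.000	0.042	58.824
Shandong	25	7	83.333	11.240	85.714
Henan	25	8	83.333	9.588	85.714
Hubei	18	8	66.667	3.077	75.000
Hunan	13	9	60.000	2.837	71.429
Guangdong	14	11	63.333	3.391	73.171
Guangxi	4	7	26.667	0.230	54.545
Hainan	0	4	13.333	0.000	50.847
Chongqing	9	9	50.000	0.847	66.667
Sichuan	9	10	50.000	0.707	66.667
Guizhou	6	9	33.333	0.114	58.824
Yunnan	4	10	36.667	0.225	61.224
Tibet	0	13	43.333	0.496	63.830
Shaanxi	9	10	50.000	1.170	66.667
Gansu	4	11	46.667	0.805	65.217
Qinghai	0	11	36.667	0.246	61.224
Ningxia	1	10	33.333	0.460	60.000
Xinjiang	1	14	50.000	1.699	66.667
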