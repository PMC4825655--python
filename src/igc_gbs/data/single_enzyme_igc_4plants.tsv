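# Single-enzyme in-silico screen over four plant genomes, as reported by a
# published GBS enzyme-screening study. count = number of DNA fragments of
# lengths 100-600 bp; igc = percent of the genome covered by those fragments.
# sl = recognition-site length. mean/sd summarise the four igc values.
enzyme	sl	arabidopsis_count	arabidopsis_igc	soybean_count	soybean_igc	rice_count	rice_igc	maize_count	maize_igc	mean	sd
CviAII	4	249612	56.7	2266324	60.7	1030613	79.0	4817820	59.6	64.0	10.1
CviKI-1	4	376984	67.3	2648781	61.9	1150523	58.9	6059914	53.9	60.5	5.6
NlaIII	4	249639	56.7	2266718	60.8	945109	62.2	4818313	59.6	59.8	2.3
MluCI	4	360972	64.7	2790706	57.9	969836	56.2	4546748	54.1	58.2	4.6
CviRI	4	244853	54.9	2194161	58.9	914234	60.1	4668840	58.6	58.1	2.2
MseI	4	349553	65.9	2583144	58.7	821137	51.2	3442333	43.4	54.8	9.7
AluI	4	253157	55.7	1410267	41.0	765561	53.7	4481014	56.5	51.7	7.2
DpnI	4	230319	52.6	1256292	38.6	680477	49.4	3833020	51.2	47.9	6.4
HinfI	5	247146	55.7	1432238	43.6	526686	39.7	3730642	50.4	47.4	7.1
Hpy188I	5	224589	51.4	1181936	35.8	574679	42.6	3713268	48.5	44.6	6.9
DdeI	5	187752	44.6	1304502	39.3	491752	37.8	3621546	49.2	42.7	5.2
BfaI	4	143863	36.0	1200979	36.5	585600	43.5	3499202	47.8	41.0	5.7
TaqI	4	172656	41.6	638273	19.9	510683	37.5	3315820	44.3	35.8	11.0
HpyCH4III	5	150724	37.7	782320	25.0	530653	40.1	2520324	36.1	34.7	6.7
RsaI	4	117822	30.2	785561	25.3	528208	39.5	2434929	35.5	32.6	6.2
TfiI	5	165612	40.1	822062	26.9	291725	23.2	1693916	25.2	28.8	7.6
HaeIII	4	41199	11.0	498808	15.1	464330	33.0	3238709	40.6	24.9	14.2
Fnu4HI	5	65979	16.8	368604	11.5	479530	32.9	2810234	35.0	24.1	11.6
HpyCH4IV	4	107461	27.1	544678	16.9	342538	26.3	1565649	22.7	23.3	4.6
Sau96I	5	39880	10.8	483707	15.0	355928	26.9	2817258	37.3	22.5	12.0
ScrFI	5	38190	10.0	289281	9.2	350643	25.9	2680165	34.3	19.9	12.3
MspI	4	46464	11.6	187972	5.8	378091	25.9	2464695	30.8	18.5	11.8
ApeKI	5	45865	12.0	257226	8.3	338090	25.2	1771780	24.6	17.5	8.6
Tsp45I	5	50386	13.5	385719	12.7	200604	16.6	1249590	18.8	15.4	2.8
HhaI	4	12350	3.4	145999	4.3	285864	19.5	2179751	26.9	13.5	11.6
BstNI	5	21241	5.7	183781	5.9	183039	14.8	1582998	22.1	12.1	7.9
AvaII	5	22727	6.3	241494	7.8	144992	11.8	1395284	20.0	11.5	6.2
AccII	4	13101	3.4	114394	3.2	247293	16.2	1539695	19.4	10.6	8.5
Hpy99I	5	19497	4.8	55184	1.6	207880	13.8	1401069	18.2	9.6	7.7
SspI	6	44863	11.4	493702	15.5	92294	7.3	213496	3.3	9.4	5.3
BstYI	6	41760	11.1	189122	6.3	105736	8.7	621055	9.9	9.0	2.0
NciI	5	6272	1.7	55716	1.9	125439	9.4	973572	13.3	6.5	5.7
PsiI	6	30444	8.0	333631	10.6	54716	4.3	127778	2.0	6.2	3.8
BsrFI	6	5528	1.4	16387	0.5	122510	8.9	413772	6.2	4.3	4.0
EcoT22I	6	9536	2.6	141415	4.6	46432	3.9	163998	2.4	3.4	1.0
NsiI	6	9536	2.6	141415	4.6	46432	3.9	163998	2.4	3.4	1.0
HindIII	6	17751	4.7	97975	3.2	17513	1.6	198699	3.3	3.2	1.3
BglII	6	8161	2.2	30497	1.0	17778	1.5	63336	1.0	1.4	0.6
EcoRI	6	5555	1.6	45234	1.5	11684	1.0	65745	1.1	1.3	0.3
NgoMIV	6	166	0.0	1436	0.0	48090	3.4	93246	1.3	1.2	1.6
SacI	6	2501	0.7	8413	0.3	20000	1.6	141985	2.1	1.2	0.8
XbaI	6	4329	1.2	36162	1.3	12426	1.1	69100	1.1	1.2	0.1
BglI	11	206	0.1	4433	0.2	27650	2.1	152478	2.3	1.2	1.2
PstI	6	3047	0.9	13079	0.4	16785	1.5	85561	1.4	1.0	0.5
EagI	6	124	0.0	3898	0.1	32765	2.5	100460	1.4	1.0	1.2
AflII	6	3637	1.0	36561	1.3	5090	0.4	61670	1.1	1.0	0.4
SphI	6	853	0.2	21649	0.8	18406	1.6	67646	1.1	0.9	0.5
AlwNI	9	2709	0.8	11631	0.4	8836	0.8	95178	1.6	0.9	0.5
BssHII	6	12	0.0	1815	0.0	24187	1.7	109573	1.6	0.9	1.0
EcoRV	6	4015	1.1	19768	0.7	9299	0.8	41023	0.7	0.8	0.2
XhoI	6	1611	0.5	8640	0.3	8925	0.7	48772	0.8	0.6	0.3
SacII	6	182	0.0	862	0.0	15281	1.1	60642	0.9	0.5	0.6
BamHI	6	1615	0.5	8977	0.3	6676	0.5	43112	0.7	0.5	0.2
SalI	6	530	0.1	5811	0.2	9303	0.7	53675	0.7	0.5	0.3
SmaI	6	148	0.0	1524	0.1	6748	0.6	56135	0.9	0.4	0.4
SgrAI	8	96	0.0	390	0.0	14315	1.1	23916	0.3	0.4	0.5
KpnI	6	429	0.1	7655	0.2	2887	0.3	28522	0.5	0.3	0.1
NotI	8	0	0.0	5	0.0	992	0.1	2278	0.0	0.0	0.0
FseI	8	3	0.0	59	0.0	749	0.1	1855	0.0	0.0	0.0
SbfI	8	2	0.0	22	0.0	88	0.0	721	0.0	0.0	0.0
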