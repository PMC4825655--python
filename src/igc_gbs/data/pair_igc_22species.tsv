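# In-silico genome coverage (IgC, %) of 22 sequenced genomes for the top 21
# enzyme pairs and the GBS reference pair PstI+MspI, as reported by a
# published GBS enzyme-screening study. Selection: fragments with different
# enzyme ends and lengths 100-600 bp.
pair	Arabidopsis	Cottonwood	Medicago	Winegrape	Soybean	Rice	Sorghum	Maize	C_elegans	Fruit_fly	Honey_bee	Stickleback	Pike	Zebra_fish	Turkey	Zebra_finch	Dog	Housecat	House_mouse	Pigmy_chimp	Opossum	Yeast
CviAII+HinfI	35.1	32.5	27.9	31.4	32.5	31.1	30.8	33.8	31.9	30.1	24.6	35.0	31.0	31.0	30.8	34.5	35.9	35.5	34.2	30.0	35.2	36.5
CviAII+DdeI	34.4	30.8	26.6	30.6	30.9	30.3	31.8	32.9	27.0	29.7	16.1	35.1	32.9	33.3	31.9	35.9	35.3	34.9	33.1	29.3	34.5	35.9
BfaI+HinfI	32.5	32.5	26.0	30.9	31.4	32.0	31.8	34.6	27.9	24.5	17.5	24.9	30.2	27.9	29.3	31.8	36.3	35.2	34.6	30.7	35.3	34.8
BfaI+DdeI	32.5	31.4	25.0	30.4	30.4	31.2	32.3	34.2	23.8	24.0	11.8	25.1	30.8	29.1	28.7	30.9	33.6	32.9	32.4	29.0	33.6	34.4
CviAII+TfiI	33.4	27.9	24.3	27.2	27.7	25.8	26.2	27.6	29.3	25.8	24.5	26.6	23.2	23.7	24.7	26.6	28.4	29.7	25.9	24.0	30.8	33.9
BfaI+TfiI	31.8	29.1	23.6	27.9	28.2	27.0	27.3	29.1	25.9	21.4	17.8	20.5	24.0	22.4	24.4	25.8	30.0	31.8	28.0	25.6	30.9	32.7
MluCI+HinfI	25.3	18.0	14.1	19.8	19.2	24.9	28.1	29.1	13.5	20.7	14.1	33.0	28.4	24.2	25.1	26.6	29.6	29.4	30.1	23.5	24.5	24.2
MluCI+DdeI	24.4	17.3	13.6	19.4	18.6	24.0	27.5	29.0	10.2	19.6	7.4	33.3	30.1	26.0	26.5	28.4	28.6	29.4	29.2	23.5	24.1	22.3
CviAII+ApeKI	19.3	17.2	12.9	13.4	14.2	25.3	22.6	23.8	18.5	27.7	11.0	33.7	25.6	26.6	28.1	31.8	24.9	23.9	25.9	21.0	20.9	25.4
HinfI+MseI	28.1	22.0	18.7	24.7	24.3	28.0	28.8	30.6	27.0	7.9	4.3	10.4	9.8	21.6	8.4	28.3	28.8	28.7	11.2	26.1	7.0	31.6
HinfI+HpyCH4IV	29.4	22.7	21.6	18.0	23.1	27.9	27.2	27.9	30.5	14.3	11.6	16.1	14.8	24.8	11.7	16.0	19.4	22.7	9.3	15.8	5.6	35.4
DdeI+MseI	27.1	20.8	17.9	24.1	23.2	26.9	29.3	30.3	21.5	8.3	3.7	10.2	9.3	22.6	6.0	29.5	29.0	29.1	7.5	25.1	5.5	30.0
MluCI+TfiI	23.7	15.0	11.8	16.6	15.9	19.9	23.3	24.6	11.8	16.9	13.1	24.8	21.0	18.4	19.6	19.8	22.7	25.3	22.6	18.5	20.4	20.6
DdeI+HpyCH4IV	29.2	22.2	20.8	17.5	22.6	27.2	27.2	27.5	26.3	14.9	9.3	15.9	13.8	26.0	8.6	14.6	18.0	20.7	6.5	14.2	4.7	35.2
ApeKI+BfaI	19.5	18.3	13.1	14.9	15.1	26.3	23.3	24.3	16.8	12.6	5.9	13.8	14.7	25.2	13.5	29.8	26.6	23.9	14.1	22.8	10.5	24.3
TfiI+HpyCH4IV	29.0	20.7	19.7	16.8	21.5	24.2	24.2	23.7	28.3	13.9	12.3	15.2	13.2	20.2	10.9	13.3	16.8	20.7	9.1	13.8	6.1	33.3
NlaIII+MluCI	25.7	19.4	16.0	20.2	19.6	25.4	27.0	29.0	13.4	5.2	2.4	10.8	7.7	27.1	6.3	28.7	29.3	30.2	8.0	24.3	5.4	24.3
TfiI+MseI	26.5	19.0	16.3	21.5	20.9	23.6	24.3	26.3	24.5	7.8	5.0	9.7	8.5	16.0	7.7	21.4	22.2	23.9	10.1	21.0	7.1	28.3
CviAII+AvaII	15.6	14.0	12.3	14.5	14.6	18.7	20.8	24.7	12.4	15.9	7.0	22.9	19.6	13.4	14.5	17.7	20.4	20.9	22.3	14.9	20.0	18.1
ApeKI+MseI	17.2	14.1	9.9	13.2	12.8	25.1	22.9	23.2	15.8	7.2	3.8	10.0	9.5	19.5	7.0	26.7	21.8	20.4	10.8	19.2	6.2	21.3
AvaII+BfaI	16.1	15.3	12.3	15.8	15.5	20.6	21.8	26.2	11.3	9.0	3.9	11.6	12.3	13.0	9.0	17.3	22.5	21.4	13.4	16.2	10.0	18.1
PstI+MspI	3.5	2.3	1.6	1.8	1.5	5.6	6.0	5.5	3.1	4.5	0.6	8.9	4.8	6.2	3.3	5.3	5.4	4.6	3.0	5.0	0.8	4.4
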