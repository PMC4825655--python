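# Empirical genome coverage (EgC, %) for three enzyme combinations
# (PM=PstI+MspI, AB=AvaII+BfaI, HH=HinfI+HpyCH4IV) in 12 plant species,
# with the per-species ratio of AB and HH to the PM reference, as printed
# in the published study. gs_mb = flow-cytometry genome size (Mb).
species	group	gs_mb	pm_egc	ab_egc	ab_ratio	hh_egc	hh_ratio
Arabidopsis_thaliana	dicot	156	0.74	2.28	3.09	4.45	6.03
Pisum_sativum	dicot	4768	0.10	0.95	9.35	0.55	5.45
Linum_grandiflorum	dicot	685	1.36	2.55	1.87	4.37	3.21
Carthamus_tinctorius	dicot	1364	0.32	1.83	5.67	1.72	5.34
Glycine_max	dicot	1100	0.71	3.33	4.67	3.33	4.67
Sinapis_alba	dicot	489	1.54	4.83	3.13	6.41	4.16
Aegilops_umbellulata	monocot	4939	0.43	0.75	1.76	0.93	2.19
Pseudoroegneria_spicata	monocot	4450	0.67	1.35	2.02	1.24	1.85
Agropyron_cristatum	monocot	6969	0.56	1.00	1.78	0.92	1.65
Zea_mays	monocot	2665	0.58	1.51	2.62	1.62	2.81
Elymus_lanceolatus	monocot	8240	0.52	0.59	1.12	0.73	1.39
Oryza_sativa	monocot	489	3.02	6.36	2.11	7.90	2.61
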