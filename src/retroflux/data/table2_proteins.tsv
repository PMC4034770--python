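# Polypeptides identified both in the silver-stained gels and in the autoradiogram.
# silver/de_novo: "+" detected, "ND" not detected. Row 29 carries the literal flag "-+"
# as printed; it is treated as silver-detected downstream.
index	protein_name	atg	mass_kda	localization	functional_role	silver	de_novo	mascot_score
1	2-Cys Peroxiredoxin	AT3G11630	22.4	Chloroplast	Defense response	+	+	66
2	3-Ketoacyl CoA thiolase 3	AT2G33150	48.6	Peroxisome	Fatty acid biosynthesis	+	+	99
3	Ascorbate peroxidase 1	AT1G07890	27.6	Cytosol	Defense response	+	+	253
4	ATP synthase delta-subunit	AT4G09650	22.8	Chloroplast	ATP synthesis	+	+	260
5	ATP synthase subunit beta	ATCG00480	47.7	Chloroplast	ATP synthesis	+	+	365
6	Carbonic anhydrase 1	AT3G01500	25.6	Chloroplast	Carbon utilization	+	+	45
7	Carbonic anhydrase 2	AT5G14740	25.1	Chloroplast	Carbon utilization	+	+	72
8	Chaperonin 60 beta	AT1G55490	58.1	Chloroplast	Protein folding	+	+	89
9	Chloroplast HSP 70-1	AT4G24280	74.6	Chloroplast	Stress response	+	+	528
10	Chloroplast HSP 70-2	AT5G49910	74.6	Chloroplast	Stress response	+	+	337
11	Cu/Zn Superoxide dismutase	AT2G28190	15.7	Chloroplast	Defense response	+	+	81
12	Cyclophilin Cyp 20-3	AT3G62030	19.7	Chloroplast	Rotamase	+	+	207
13	Dehydroascorbate reductase	AT1G19570	21.7	Cytosolic	Defense response	+	+	93
14	D-Ribulose-5-P epimerase	AT5G61410	28	Chloroplast	Calvin cycle	+	ND	154
15	Fructose-bisphosphate aldolase 1	AT2G21330	41.9	Chloroplast	Calvin cycle	+	+	91
16	Fructose-bisphosphate aldolase 2	AT4G38970	38	Chloroplast	Calvin cycle	+	+	106
17	GAP C2 subunit	AT1G13440	36.9	Cytosol	Oxidoreductase	+	+	164
18	Germin 3 oxalate oxidase	AT5G20630	19.5	Apoplast	Defense response	+	ND	243
19	Glutamine synthetase 2	AT5G35630	42.5	Chloro/Mito	Glutamine biosynthesis	+	+	141
20	Glutathione S-transferase F8	AT2G47730	23.9	Chloroplast	Stress response	+	ND	71
21	Glutathione S-transferase F9	AT2G30860	24.2	Cytosol	Stress response	+	ND	118
22	Glyceraldehyde-3-P-DH, B subunit	AT1G42970	39.3	Chloroplast	Calvin cycle	+	+	70
23	HCF 136	AT5G23120	38.5	Chloroplast	Photosynthesis	+	+	173
24	Lactate/malate dehydrogenase	AT1G53240	33.2	Mitochond.	TCA-cycle	+	+	65
25	Malate dehydrogenase	AT3G47520	34	Chloroplast	Redox metabolism	+	+	107
26	Manganese SOD	AT3G10920	22.2	Mitochond	Defence response	+	ND	78
27	O-Acetyl serine thiol lyase B	AT2G43750	35.1	Chloroplast	Cysteine biosynthesis	+	+	85
28	Phosphoglycerate kinase 1	AT1G79550	42.63	Chloroplast	Calvin cycle	+	+	86
29	Phosphoglycerate mutase	AT3G08590	60.7	Cytosol	Glycolysis	-+	+	143
30	Phosphoribulokinase	AT1G32060	39.2	Chloroplast	Calvin cycle	+	+	97
31	Plastid-lipid-associated protein 1	AT4G04020	34.9	Chloroplast	Stress response	+	+	113
32	Plastocyanin (DRT 112)	AT1G20340	10.5	Chloroplast	Electron transport	+	ND	169
33	PSII oxygen evolving complex	AT5G66570	26.5	Chloroplast	Photosynthesis	+	+	114
34	PSII, subunit PSB-O2	AT3G50820	35.0	Chloroplast	Photosynthesis	+	+	304
35	PSII subunit P-1	AT1G06680	20.2	Chloroplast	Photosynthesis	+	+	183
36	Ribose 5-phosphate isomerase	AT3G04790	27.1	Chloroplast	Calvin cycle	+	ND	161
37	Ribosomal protein S1	AT5G30510	40.5	Chloroplast	RNA binding	+	+	70
38	RPL12 | ribosomal protein L12-A	AT3G27830	14	Chloroplast	Translation	+	+	78
39	Rubisco activase	AT2G39730	46.2	Chloroplast	Calvin cycle	+	+	462
40	RubisCO large subunit	ATCG00490	53	Chloroplast	Calvin cycle	+	+	304
41	RubisCO small subunit 1A	AT1G67090	14.7	Chloroplast	Calvin cycle	+	+	346
42	RubisCO small subunit 1B	AT5G38430	14.8	Chloroplast	Calvin cycle	+	+	71
43	RubisCO small subunit 2B	AT5G38420	14.8	Chloroplast	Calvin cycle	+	+	308
44	S-Adenosylmethionine synthetase 1	AT1G02500	43.2	Cytoplasm	Met adenos.transferase	+	ND	92
45	Sedoheptulose-bisphosphatase	AT3G55800	36.1	Chloroplast	Calvin cycle	+	+	229
46	Stromal APx	AT4G08390	37.8	Chloroplast	Defense response	+	+	67
47	Thioredoxin m1	AT1G03680	12.4	Chloroplast	Defense response	+	+	105
48	Thioredoxin m2	AT4G03520	12.5	Chloroplast	Defense response	+	+	72
49	Triose phosphate isomerase	AT2G21170	27	Chloroplast	Calvin cycle	+	+	133
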