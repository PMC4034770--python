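# De novo synthesized proteins with identified functional assignment, grouped into the
# four regulation archetypes plus the "no peculiar group pattern" remainder.
# member_name/functional_role are literal; table2_match is a best-effort mapping onto a
# protein_name from the identified-polypeptide table. The source table is internally
# loose on malate dehydrogenase naming: "Malate DH cyt" (cluster 4) and "Malate DH, cp"
# (none) both match the chloroplast malate dehydrogenase entry; RubisCO SSU 1B/2B are
# assigned to no cluster.
cluster	response_pattern	member_name	functional_role	table2_match
1	L→H & N→H low	DHAR	Antioxidant defence	Dehydroascorbate reductase
1	L→H & N→H low	GAPDH B subunit	Photosynthesis	Glyceraldehyde-3-P-DH, B subunit
1	L→H & N→H low	PSII subunit O-2	Photosynthesis	PSII, subunit PSB-O2
1	L→H & N→H low	PSII subunit P-1	Photosynthesis	PSII subunit P-1
1	L→H & N→H low	Ribose 5-P isomerase A	Photosynthesis	Ribose 5-phosphate isomerase
1	L→H & N→H low	RPL12, ribosomal protein	Protein synthesis	RPL12 | ribosomal protein L12-A
1	L→H & N→H low	SOD, Cu/Zn	Antioxidant defence	Cu/Zn Superoxide dismutase
1	L→H & N→H low	Thioredoxin m2	Redox regulation	Thioredoxin m2
2	L→H & N→H high	Carbonic anhydrase 2	Photosynthesis	Carbonic anhydrase 2
2	L→H & N→H high	Chaperonin 60 beta	Protein folding	Chaperonin 60 beta
2	L→H & N→H high	FBP aldolase 1	Photosynthesis	Fructose-bisphosphate aldolase 1
2	L→H & N→H high	FBP aldolase 2	Photosynthesis	Fructose-bisphosphate aldolase 2
2	L→H & N→H high	HCF 136	Photosynthesis	HCF 136
2	L→H & N→H high	HSP 70-1, cp	Stress response	Chloroplast HSP 70-1
2	L→H & N→H high	Lactate/malate DH	Respiration	Lactate/malate dehydrogenase
2	L→H & N→H high	O-Acetyl serine thiol lyase B	Sulfur metabolism	O-Acetyl serine thiol lyase B
3	N→H high, L→H low	3-Ketoacyl CoA thiolase 3	Fatty acid metabolism	3-Ketoacyl CoA thiolase 3
3	N→H high, L→H low	GAP C2 subunit	Photosynthesis	GAP C2 subunit
3	N→H high, L→H low	Glutamine synthetase 2	Nitrogen metabolism	Glutamine synthetase 2
3	N→H high, L→H low	Phosphoglycerate kinase 1	Photosynthesis	Phosphoglycerate kinase 1
3	N→H high, L→H low	Phosphoribulo kinase	Photosynthesis	Phosphoribulokinase
3	N→H high, L→H low	Rubisco activase	Photosynthesis	Rubisco activase
3	N→H high, L→H low	Plastid-lipid-associated protein 1	Stress response	Plastid-lipid-associated protein 1
3	N→H high, L→H low	RubisCO SU 1A	Photosynthesis	RubisCO small subunit 1A
3	N→H high, L→H low	SBPase	Photosynthesis	Sedoheptulose-bisphosphatase
3	N→H high, L→H low	SAM synthetase 1	Sulfur metabolism	S-Adenosylmethionine synthetase 1
4	N, N→H high; L, L→H low	ATP synthase beta	Photosynthesis	ATP synthase subunit beta
4	N, N→H high; L, L→H low	ATP synthase delta	Photosynthesis	ATP synthase delta-subunit
4	N, N→H high; L, L→H low	APX 1	Antioxidant defence	Ascorbate peroxidase 1
4	N, N→H high; L, L→H low	APx, stromal, cp	Antioxidant defence	Stromal APx
4	N, N→H high; L, L→H low	Carbonic anhydrase 1	Photosynthesis	Carbonic anhydrase 1
4	N, N→H high; L, L→H low	Cyclophilin Cyp 20-3	Redox regulation	Cyclophilin Cyp 20-3
4	N, N→H high; L, L→H low	Malate DH cyt	Redox regulation	Malate dehydrogenase
4	N, N→H high; L, L→H low	PSII OEC	Photosynthesis	PSII oxygen evolving complex
none	no peculiar group pattern	2-Cys Peroxiredoxin	Antioxidant defence	2-Cys Peroxiredoxin
none	no peculiar group pattern	Germin 3 oxalate oxidase	Stress defence	Germin 3 oxalate oxidase
none	no peculiar group pattern	GST F8	Stress defence	Glutathione S-transferase F8
none	no peculiar group pattern	GST F9	Stress defence	Glutathione S-transferase F9
none	no peculiar group pattern	HSP 70-2, cp	Stress defence	Chloroplast HSP 70-2
none	no peculiar group pattern	Malate DH, cp	Redox regulation	Malate dehydrogenase
none	no peculiar group pattern	Mn SOD	Antioxidant defence	Manganese SOD
none	no peculiar group pattern	Phosphoglycerate mutase	Glycolysis	Phosphoglycerate mutase
none	no peculiar group pattern	Plastocyanin (DRT 112)	Photosynthesis	Plastocyanin (DRT 112)
none	no peculiar group pattern	Ribosomal protein S1	Protein synthesis	Ribosomal protein S1
none	no peculiar group pattern	RubisCo large subunit	Photosynthesis	RubisCO large subunit
none	no peculiar group pattern	Ribulose-5-P epimerase	Photosynthesis	D-Ribulose-5-P epimerase
none	no peculiar group pattern	Thioredoxin m1	Redox regulation	Thioredoxin m1
none	no peculiar group pattern	Triosephosphate isomerase	Photosynthesis	Triose phosphate isomerase
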