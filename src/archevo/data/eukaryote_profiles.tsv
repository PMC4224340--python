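taxon	profile	note
Acanthamoeba_castellanii	B-K-P	Amorphea table row
Copromyxa_protea	B-K-P	Amorphea table row
Dictyostelium_discoideum	B-K-P	Amorphea table row
Dictyostelium_purpureum	B-K-P	Amorphea table row
Pygsuia_biforma	.	Amorphea table row
Thecamonas_trahens	.	Amorphea table row
Sphaeroforma_arctica	B-B;K-P	Amorphea table row
Capsaspora_owczarzaki	B-B;K-P	Amorphea table row
Choanoflagellata_rep	.	Amorphea table row
Metazoa_rep	.	Amorphea table row
Fonticula_alba	B-B-K-P	Amorphea table row
Saccharomyces_cerevisiae	B-B-K-P	Amorphea table row
Aspergillus_carbonarius	B;K-P	Amorphea table row
Coccidioides_immitis	B;K-P	Amorphea table row
Cochliobolus_heterostrophus	B-B;K-P	Amorphea table row
Cladonia_grayi	B-B;K-P	Amorphea table row
Chaetomium_globosum	B-B;K-P	Amorphea table row
Neurospora_crassa	B-B;K-P	Amorphea table row
Wallemia_sebi	K-P	Amorphea table row
Puccinia_graminis	B-B;K-P	Amorphea table row
Melampsora_laricis_populina	B-K-P	Amorphea table row
Postia_placenta	B-K-P	Amorphea table row
Laccaria_bicolor	K-P	Amorphea table row
Coprinopsis_cinerea	B-K-P	Amorphea table row
Branchiostoma_floridae	B-K	animal folB-folK of likely prokaryotic origin (horizontal acquisition); kept in the eukaryote-wide table only
SAR_rep	K-P	representative Diaphoretickes lineage; folK-folP fusion, folB not identified
Cryptophyta_rep	K-P	representative Diaphoretickes lineage; folK-folP fusion, folB not identified
Arabidopsis_thaliana	K-P;B	folK-folP fusion plus a standalone folB xenologue of bacterial affinity
Trypanosoma_rep	.	excavate; pathway absent, folate salvage inferred
Naegleria_rep	.	excavate; pathway absent, folate salvage inferred
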