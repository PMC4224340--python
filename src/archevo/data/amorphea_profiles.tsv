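taxon	profile	note
Acanthamoeba_castellanii	B-K-P	triple fusion confirmed by cDNA in the amoebozoan case organism
Copromyxa_protea	B-K-P	amoebozoan triple fusion
Dictyostelium_discoideum	B-K-P	amoebozoan triple fusion
Dictyostelium_purpureum	B-K-P	amoebozoan triple fusion (search seed genome)
Pygsuia_biforma	.	breviate; pterin-branch genes not found in RNA-seq survey
Thecamonas_trahens	.	apusomonad; pathway absent, folate salvage inferred
Sphaeroforma_arctica	B-B;K-P	holozoan; separated tandem-folB and folK-folP genes
Capsaspora_owczarzaki	B-B;K-P	holozoan; separated tandem-folB and folK-folP genes
Choanoflagellata_rep	.	representative; pterin branch absent
Metazoa_rep	.	representative; pterin branch absent from sampled animals
Fonticula_alba	B-B-K-P	sorocarpic opisthokont protist with the four-domain fusion
Saccharomyces_cerevisiae	B-B-K-P	fungal four-domain fusion
Aspergillus_carbonarius	B;K-P	ascomycete; single folB after contraction of the tandem
Coccidioides_immitis	B;K-P	ascomycete; single folB after contraction of the tandem
Cochliobolus_heterostrophus	B-B;K-P	pezizomycotine ascomycete; separated genes
Cladonia_grayi	B-B;K-P	pezizomycotine ascomycete; separated genes
Chaetomium_globosum	B-B;K-P	pezizomycotine ascomycete; separated genes
Neurospora_crassa	B-B;K-P	pezizomycotine ascomycete; separated genes
Wallemia_sebi	K-P	basidiomycete; both folB domains lost
Puccinia_graminis	B-B;K-P	basidiomycete; separated genes
Melampsora_laricis_populina	B-K-P	basidiomycete; one folB domain lost from the fusion
Postia_placenta	B-K-P	basidiomycete; one folB domain lost from the fusion
Laccaria_bicolor	K-P	basidiomycete; both folB domains lost
Coprinopsis_cinerea	B-K-P	basidiomycete; one folB domain lost from the fusion
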