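child_node	event_type	inputs	outputs	detail	note
(root)	root_state		B-K-P		triple fusion present in the common ancestor of Amoebozoa and Opisthokonta
Opisthokonta	duplication	B-K-P	B-B-K-P	0:1	tandem folB duplication on the opisthokont stem (D)
Sphaeroforma_arctica	separation	B-B-K-P	B-B;K-P	2	fission by ORF separation (F1)
Capsaspora_owczarzaki	separation	B-B-K-P	B-B;K-P	2	fission by ORF separation (F2)
Pezizomycotina	separation	B-B-K-P	B-B;K-P	2	fission by ORF separation before the pezizomycotine radiation (F3)
Puccinia_graminis	separation	B-B-K-P	B-B;K-P	2	fission by ORF separation (F4)
Coprinopsis_cinerea	deletion	B-B-K-P	B-K-P	0:1	fission by loss of one folB domain (FL)
Laccaria_bicolor	deletion	B-B-K-P	K-P	0:2	fission by loss of both folB domains (FL)
Wallemia_sebi	deletion	B-B-K-P	K-P	0:2	fission by loss of both folB domains (FL)
Postia_placenta	deletion	B-B-K-P	B-K-P	0:1	fission by loss of one folB domain (FL)
Melampsora_laricis_populina	deletion	B-B-K-P	B-K-P	0:1	fission by loss of one folB domain (FL)
Eurotiomycetes	deletion	B-B	B	0:1	contraction of the standalone tandem folB gene (not a fission)
Thecamonas_trahens	loss	B-K-P	.		whole-pathway loss
Pygsuia_biforma	loss	B-K-P	.		whole-pathway loss
Choanozoa	loss	B-B-K-P	.		whole-pathway loss on the choanoflagellate+animal stem
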