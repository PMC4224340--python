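(((Acanthamoeba_castellanii,Copromyxa_protea),(Dictyostelium_discoideum,Dictyostelium_purpureum))Amoebozoa,(Pygsuia_biforma,(Thecamonas_trahens,((Sphaeroforma_arctica,(Capsaspora_owczarzaki,(Choanoflagellata_rep,Metazoa_rep)Choanozoa)Filozoa)Holozoa,(Fonticula_alba,((Saccharomyces_cerevisiae,((Aspergillus_carbonarius,Coccidioides_immitis)Eurotiomycetes,(Cochliobolus_heterostrophus,(Cladonia_grayi,(Chaetomium_globosum,Neurospora_crassa))))Pezizomycotina)Ascomycota,(Wallemia_sebi,((Puccinia_graminis,Melampsora_laricis_populina)Pucciniomycotina,(Postia_placenta,(Laccaria_bicolor,Coprinopsis_cinerea))Agaricomycotina))Basidiomycota)Fungi)Holomycota)Opisthokonta))Obazoa)Amorphea;
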