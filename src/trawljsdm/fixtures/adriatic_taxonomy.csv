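species,phylum,class,order,family,genus,species_epithet
Scyliorhinus_canicula,Chordata,Chondrichthyes,Carcharhiniformes,Scyliorhinidae,Scyliorhinus,canicula
Raja_miraletus,Chordata,Chondrichthyes,Rajiformes,Rajidae,Raja,miraletus
Squalus_acanthias,Chordata,Chondrichthyes,Squaliformes,Squalidae,Squalus,acanthias
Raja_clavata,Chordata,Chondrichthyes,Rajiformes,Rajidae,Raja,clavata
Mustelus_spp,Chordata,Chondrichthyes,Carcharhiniformes,Triakidae,Mustelus,spp
Myliobatis_aquila,Chordata,Chondrichthyes,Myliobatiformes,Myliobatidae,Myliobatis,aquila
Torpedo_marmorata,Chordata,Chondrichthyes,Torpediniformes,Torpedinidae,Torpedo,marmorata
Raja_asterias,Chordata,Chondrichthyes,Rajiformes,Rajidae,Raja,asterias
Scyliorhinus_stellaris,Chordata,Chondrichthyes,Carcharhiniformes,Scyliorhinidae,Scyliorhinus,stellaris
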