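species,common_name,age_maturity,repro_mode,trophic_level
Scyliorhinus_canicula,small-spotted catshark,5.0,oviparous,3.60
Raja_miraletus,brown skate,2.5,oviparous,3.67
Squalus_acanthias,spurdog,15.0,viviparous,3.90
Raja_clavata,thornback skate,7.5,oviparous,3.69
Mustelus_spp,smooth-hound,10.5,viviparous,3.80
Myliobatis_aquila,common eagle ray,3.0,viviparous,3.33
Torpedo_marmorata,marbled torpedo,12.0,viviparous,4.24
Raja_asterias,starry skate,3.5,oviparous,3.82
Scyliorhinus_stellaris,nursehound,5.0,oviparous,4.00
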