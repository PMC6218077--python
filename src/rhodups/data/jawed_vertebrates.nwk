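((Scyliorhinus,Raja)Chondrichthyes,((Latimeria,(Protopterus,Homo))Sarcopterygii,(Polypterus,((Acipenser,(Amia,Lepisosteus))NonTeleostNeopterygii,((Elops,(Albula,(Notacanthus,(Anguilla,Conger)Anguilliformes)))Elopomorpha,((Hiodon,(Scleropages,Pantodon))Osteoglossomorpha,((Clupea,(Danio,Astyanax))Otocephala,(Oryzias,(Takifugu,Gasterosteus))Euteleostei)Clupeocephala)Osteoglossocephala)Teleostei)ActinopteriCrown)Actinopterygii)Osteichthyes)Gnathostomata;
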