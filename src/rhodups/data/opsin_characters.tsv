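taxon	exo_rh1_presence	rh1_intron_presence	intronless_rh1_copies
Scyliorhinus	0	1	0
Raja	0	1	0
Latimeria	0	1	0
Protopterus	0	1	0
Homo	0	1	0
Polypterus	?	?	?
Acipenser	?	0	1
Amia	?	0	1
Lepisosteus	1	0	1
Elops	?	0	1
Albula	?	0	1
Notacanthus	?	0	1
Anguilla	1	0	2
Conger	1	0	2
Hiodon	?	0	2
Scleropages	1	0	1
Pantodon	?	0	1
Clupea	?	0	2
Danio	1	0	2
Astyanax	1	0	2
Oryzias	1	0	1
Takifugu	1	0	1
Gasterosteus	1	0	1
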