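# The 22 sequenced genomes assayed in the published pair screen:
# taxonomic group and reported genome size (Mb).
species	group	genome_size_mb
Arabidopsis	plant	120
Cottonwood	plant	379
Medicago	plant	297
Winegrape	plant	426
Soybean	plant	950
Rice	plant	382
Sorghum	plant	659
Maize	plant	2060
C_elegans	animal	83
Fruit_fly	animal	158
Honey_bee	animal	220
Stickleback	animal	401
Pike	animal	377
Zebra_fish	animal	1340
Turkey	animal	1040
Zebra_finch	animal	1021
Dog	animal	2328
Housecat	animal	2419
House_mouse	animal	2726
Pigmy_chimp	animal	3152
Opossum	animal	2998
Yeast	fungus	12
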