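class_name	unique_a	redundant_a	unique_b	redundant_b
rRNA	121157	1206590	95822	1048627
tRNA	63757	909903	37194	883721
snRNA	2545	5576	2324	5358
snoRNA	907	3011	814	2786
conserved_miRNA	451	247850	470	116004
novel_miRNA	221	72569	219	65939
unannotated	3444360	9658708	2947259	9169583
total	3633398	12104207	3084102	11292018
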