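class	order	family	final_identification	dung_associated	grassland	meadow	forest	reads
Arachnida	Mesostigmata	Macrochelidae	Macrocheles sp.	Indirectly				18027
Arachnida	Sarcoptiformes	Ceratozetidae	Trichoribates incisellus	Indirectly		x	x	158
Arachnida	Sarcoptiformes	Chamobatidae	Chamobates birulai	Indirectly			x	313
Arachnida	Sarcoptiformes	NA	Sarcoptiformes sp.	-				16
Collembola	Entomobryomorpha	Entomobryidae	Entomobrya sp.	Indirectly				73
Collembola	Entomobryomorpha	Isotomidae	Desoria grisea	Indirectly			x	409
Collembola	Entomobryomorpha	Isotomidae	Isotomurus fucicolus	Indirectly			x	6
Collembola	Poduromorpha	Hypogastruridae	Ceratophysella denticulata	Indirectly			x	922
Collembola	Poduromorpha	Hypogastruridae	Hypogastrura assimilis	Indirectly	x	x	x	6601
Collembola	Symphypleona	Sminthuridae	Sminthurus viridis	Indirectly	x			79
Insecta	Coleoptera	Curculionidae	Hypera plantaginis	No	x	x	x	50
Insecta	Coleoptera	Histeridae	Margarinotus ventralis	Yes	x	x		982
Insecta	Coleoptera	Hydrophilidae	Cercyon haemorrhoidalis	Yes	x			211
Insecta	Coleoptera	Hydrophilidae	Cercyon pygmaeus	Yes	x			218
Insecta	Coleoptera	Hydrophilidae	Cercyon quisquilius	Yes	x			188
Insecta	Coleoptera	Hydrophilidae	Sphaeridium bipustulatum	Yes	x			96
Insecta	Coleoptera	Hydrophilidae	Sphaeridium lunatum	Yes	x	x		6172
Insecta	Coleoptera	Hydrophilidae	Sphaeridium scarabaeoides	Yes	x	x		595
Insecta	Coleoptera	Phalacridae	Olibrus sp.	No				5842
Insecta	Coleoptera	Scarabaeidae	Aphodius depressus	Yes			x	432
Insecta	Coleoptera	Scarabaeidae	Aphodius haemorrhoidalis	Yes	x	x		4706
Insecta	Coleoptera	Scarabaeidae	Aphodius sphacelatus	Yes		x		21
Insecta	Coleoptera	Scarabaeidae	Aphodius sticticus	Yes			x	17
Insecta	Coleoptera	Staphylinidae	Oxytelus laqueatus	Yes			x	8976
Insecta	Dermaptera	Forficulidae	Forficula auricularia	Indirectly	x			16
Insecta	Diptera	Anisopodidae	Sylvicola sp.	Yes				1867
Insecta	Diptera	Anthomyiidae	Hylemya vagans	Yes			x	1139
Insecta	Diptera	Chironomidae	Smittia sp.	Yes				178
Insecta	Diptera	Muscidae	Azelia nebulosa	Yes			x	268
Insecta	Diptera	Muscidae	Haematobia irritans	Yes	x	x		550
Insecta	Diptera	Muscidae	Hebecnema umbratica	Yes		x	x	1423
Insecta	Diptera	Muscidae	Mesembrina meridiana	Yes		x		10
Insecta	Diptera	Muscidae	Musca autumnalis	Yes	x	x		102361
Insecta	Diptera	Muscidae	Mydaea urbana	Yes			x	213
Insecta	Diptera	Muscidae	Neomyia cornicina	Yes	x	x		30027
Insecta	Diptera	NA	Diptera sp.	-				14
Insecta	Diptera	Psychodidae	Psychoda grisescens	Yes			x	147
Insecta	Diptera	Psychodidae	Psychoda phalaenoides	Yes		x	x	239498
Insecta	Diptera	Psychodidae	Psychoda setigera	Yes	x		x	6158
Insecta	Diptera	Psychodidae	Psychoda trinodulosa	Yes	x	x	x	17653
Insecta	Diptera	Scathophagidae	Scathophaga stercoraria	Yes	x	x		2812
Insecta	Diptera	Sepsidae	Saltella sphondylii	Yes	x	x		23025
Insecta	Diptera	Sepsidae	Sepsis sp.	Yes				11867
Insecta	Diptera	Sepsidae	Sepsis cynipsea	Yes	x	x		86068
Insecta	Diptera	Sepsidae	Sepsis duplicata	Yes	x	x		2058
Insecta	Diptera	Sepsidae	Sepsis thoracica	Yes	x	x		1153
Insecta	Diptera	Sphaeroceridae	Coproica lugubris	Yes	x	x		802
Insecta	Diptera	Sphaeroceridae	Norrbomia sordida	Yes		x		77
Insecta	Diptera	Sphaeroceridae	Lotophila atra	Yes	x	x	x	7885
Insecta	Diptera	Sphaeroceridae	Spelobia clunipes	Yes	x	x	x	58006
Insecta	Diptera	Stratiomyidae	Microchrysa polita	Yes	x			1869
Insecta	Hemiptera	Aphididae	Euceraphis betulae	No			x	11
Insecta	Hemiptera	Miridae	Rhabdomiris striatellus	No	x			55
Insecta	Hemiptera	Pentatomidae	Dolycoris sp.	No				79
Insecta	Hymenoptera	Formicidae	Lasius niger	No	x			24
Insecta	Phthiraptera	Bovicoliidae	Bovicola bovis	Cow parasite	x			38
Chromadorea	Strongylida	Ancylostomatidae	Bunostomum phlebotomum	Cow parasite		x	x	29
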