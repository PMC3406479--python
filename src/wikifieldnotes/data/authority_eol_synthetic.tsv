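identifier	scientific_name	rank	accepted	vernaculars	kingdom	phylum	class	order	family	genus
EOL-1046714	Sayornis saya	species	true	Say's Phoebe|Say Phoebe	Animalia	Chordata	Aves	Passeriformes	Tyrannidae	Sayornis
EOL-1051079	Carduelis pinus	species	true	Pine Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Carduelis
EOL-1177498	Turdus migratorius	species	true	American Robin|robin	Animalia	Chordata	Aves	Passeriformes	Turdidae	Turdus
EOL-1177920	Colaptes auratus	species	true	Northern Flicker|flicker	Animalia	Chordata	Aves	Piciformes	Picidae	Colaptes
EOL-1177505	Pica hudsonia	species	true	Black-billed Magpie|magpie	Animalia	Chordata	Aves	Passeriformes	Corvidae	Pica
EOL-1177439	Cyanocitta stelleri	species	true	Steller's Jay	Animalia	Chordata	Aves	Passeriformes	Corvidae	Cyanocitta
EOL-1052333	Sturnella neglecta	species	true	Western Meadowlark|meadowlark	Animalia	Chordata	Aves	Passeriformes	Icteridae	Sturnella
EOL-1049698	Zenaida macroura	species	true	Mourning Dove	Animalia	Chordata	Aves	Columbiformes	Columbidae	Zenaida
EOL-1049202	Buteo jamaicensis	species	true	Red-tailed Hawk	Animalia	Chordata	Aves	Accipitriformes	Accipitridae	Buteo
EOL-1177508	Corvus corax	species	true	Common Raven|raven	Animalia	Chordata	Aves	Passeriformes	Corvidae	Corvus
EOL-1052016	Junco hyemalis	species	true	Dark-eyed Junco|junco	Animalia	Chordata	Aves	Passeriformes	Passerellidae	Junco
EOL-1050675	Sitta carolinensis	species	true	White-breasted Nuthatch|nuthatch	Animalia	Chordata	Aves	Passeriformes	Sittidae	Sitta
EOL-1064539	Anas platyrhynchos	species	true	Mallard	Animalia	Chordata	Aves	Anseriformes	Anatidae	Anas
EOL-1048653	Ardea herodias	species	true	Great Blue Heron|heron	Animalia	Chordata	Aves	Pelecaniformes	Ardeidae	Ardea
EOL-328653	Odocoileus hemionus	species	true	Mule Deer|deer	Animalia	Chordata	Mammalia	Artiodactyla	Cervidae	Odocoileus
EOL-328471	Castor canadensis	species	true	American Beaver|beaver	Animalia	Chordata	Mammalia	Rodentia	Castoridae	Castor
EOL-347433	Sciurus aberti	species	true	Abert's Squirrel|squirrel	Animalia	Chordata	Mammalia	Rodentia	Sciuridae	Sciurus
EOL-326997	Ochotona princeps	species	true	American Pika|pika	Animalia	Chordata	Mammalia	Lagomorpha	Ochotonidae	Ochotona
EOL-61747	Populus	genus	true	cottonwood|poplar	Plantae	Tracheophyta	Magnoliopsida	Malpighiales	Salicaceae	Populus
EOL-1061748	Pinus ponderosa	species	true	Ponderosa Pine	Plantae	Tracheophyta	Pinopsida	Pinales	Pinaceae	Pinus
EOL-1061658	Picea engelmannii	species	true	Engelmann Spruce|spruce	Plantae	Tracheophyta	Pinopsida	Pinales	Pinaceae	Picea
EOL-1061734	Pseudotsuga menziesii	species	true	Douglas-fir	Plantae	Tracheophyta	Pinopsida	Pinales	Pinaceae	Pseudotsuga
EOL-4919229	Oreohelix strigosa	species	true	Rocky Mountain snail|snail	Animalia	Mollusca	Gastropoda	Stylommatophora	Oreohelicidae	Oreohelix
EOL-452351	Physa gyrina	species	true	tadpole snail	Animalia	Mollusca	Gastropoda	Hygrophila	Physidae	Physa
EOL-395049	Amphipyra tragopoginis	species	true	Mouse Moth|mouse	Animalia	Arthropoda	Insecta	Lepidoptera	Noctuidae	Amphipyra
EOL-16498	Crucibulum	genus	true	bird's nest fungus	Fungi	Basidiomycota	Agaricomycetes	Agaricales	Nidulariaceae	Crucibulum
EOL-917146	Selasphorus platycercus	species	true	Broad-tailed Hummingbird|hummingbird	Animalia	Chordata	Aves	Apodiformes	Trochilidae	Selasphorus
EOL-205418	Salvelinus fontinalis	species	true	Brook Trout|trout	Animalia	Chordata	Actinopterygii	Salmoniformes	Salmonidae	Salvelinus
EOL-311544	Cynomys ludovicianus	species	true	Black-tailed Prairie Dog|prairie dog	Animalia	Chordata	Mammalia	Rodentia	Sciuridae	Cynomys
EOL-596887	Aquilegia coerulea	species	true	Colorado Blue Columbine|columbine	Plantae	Tracheophyta	Magnoliopsida	Ranunculales	Ranunculaceae	Aquilegia
EOL-2866650	Planesticus migratorius	species	false	robin	Animalia	Chordata	Aves	Passeriformes	Turdidae	Planesticus
EOL-1051078	Spinus spinus	species	true	Eurasian Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051080	Spinus atratus	species	true	Black Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051081	Spinus crassirostris	species	true	Thick-billed Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051082	Spinus barbatus	species	true	Black-chinned Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051083	Spinus olivaceus	species	true	Olivaceous Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051084	Spinus magellanicus	species	true	Hooded Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051085	Spinus siemiradzkii	species	true	Saffron Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051086	Spinus yarrellii	species	true	Yellow-faced Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051087	Spinus cucullatus	species	true	Red Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051088	Spinus dominicensis	species	true	Antillean Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051089	Spinus atriceps	species	true	Black-capped Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051090	Spinus notatus	species	true	Black-headed Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051091	Spinus xanthogastrus	species	true	Yellow-bellied Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051092	Spinus spinescens	species	true	Andean Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051093	Spinus uropygialis	species	true	Yellow-rumped Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Spinus
EOL-1051094	Serinus thibetanus	species	true	Tibetan Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Serinus
EOL-1051095	Carduelis spinoides	species	true	Himalayan Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Carduelis
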