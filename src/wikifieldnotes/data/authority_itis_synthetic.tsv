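identifier	scientific_name	rank	accepted	vernaculars	kingdom	phylum	class	order	family	genus
178344	Sayornis saya	species	true	Say's Phoebe|Say Phoebe	Animalia	Chordata	Aves	Passeriformes	Tyrannidae	Sayornis
179233	Carduelis pinus	species	true	Pine Siskin|siskin	Animalia	Chordata	Aves	Passeriformes	Fringillidae	Carduelis
179759	Turdus migratorius	species	true	American Robin|robin	Animalia	Chordata	Aves	Passeriformes	Turdidae	Turdus
178154	Colaptes auratus	species	true	Northern Flicker|flicker	Animalia	Chordata	Aves	Piciformes	Picidae	Colaptes
916341	Pica hudsonia	species	true	Black-billed Magpie|magpie	Animalia	Chordata	Aves	Passeriformes	Corvidae	Pica
179725	Cyanocitta stelleri	species	true	Steller's Jay	Animalia	Chordata	Aves	Passeriformes	Corvidae	Cyanocitta
179932	Sturnella neglecta	species	true	Western Meadowlark|meadowlark	Animalia	Chordata	Aves	Passeriformes	Icteridae	Sturnella
177125	Zenaida macroura	species	true	Mourning Dove	Animalia	Chordata	Aves	Columbiformes	Columbidae	Zenaida
175350	Buteo jamaicensis	species	true	Red-tailed Hawk	Animalia	Chordata	Aves	Accipitriformes	Accipitridae	Buteo
179725b	Corvus corax	species	true	Common Raven|raven	Animalia	Chordata	Aves	Passeriformes	Corvidae	Corvus
179410	Junco hyemalis	species	true	Dark-eyed Junco|junco	Animalia	Chordata	Aves	Passeriformes	Passerellidae	Junco
178775	Sitta carolinensis	species	true	White-breasted Nuthatch|nuthatch	Animalia	Chordata	Aves	Passeriformes	Sittidae	Sitta
175063	Anas platyrhynchos	species	true	Mallard	Animalia	Chordata	Aves	Anseriformes	Anatidae	Anas
174773	Ardea herodias	species	true	Great Blue Heron|heron	Animalia	Chordata	Aves	Pelecaniformes	Ardeidae	Ardea
180698	Odocoileus hemionus	species	true	Mule Deer|deer	Animalia	Chordata	Mammalia	Artiodactyla	Cervidae	Odocoileus
180212	Castor canadensis	species	true	American Beaver|beaver	Animalia	Chordata	Mammalia	Rodentia	Castoridae	Castor
180170	Sciurus aberti	species	true	Abert's Squirrel|squirrel	Animalia	Chordata	Mammalia	Rodentia	Sciuridae	Sciurus
180111	Ochotona princeps	species	true	American Pika|pika	Animalia	Chordata	Mammalia	Lagomorpha	Ochotonidae	Ochotona
22444	Populus	genus	true	cottonwood|poplar	Plantae	Tracheophyta	Magnoliopsida	Malpighiales	Salicaceae	Populus
183365	Pinus ponderosa	species	true	Ponderosa Pine	Plantae	Tracheophyta	Pinopsida	Pinales	Pinaceae	Pinus
183291	Picea engelmannii	species	true	Engelmann Spruce|spruce	Plantae	Tracheophyta	Pinopsida	Pinales	Pinaceae	Picea
183424	Pseudotsuga menziesii	species	true	Douglas-fir	Plantae	Tracheophyta	Pinopsida	Pinales	Pinaceae	Pseudotsuga
77061	Oreohelix strigosa	species	true	Rocky Mountain snail|snail	Animalia	Mollusca	Gastropoda	Stylommatophora	Oreohelicidae	Oreohelix
76605	Physa gyrina	species	true	tadpole snail	Animalia	Mollusca	Gastropoda	Hygrophila	Physidae	Physa
180366	Mus musculus	species	true	house mouse|mouse	Animalia	Chordata	Mammalia	Rodentia	Muridae	Mus
72519	Crucibulum	genus	true	cup-and-saucer snail	Animalia	Mollusca	Gastropoda	Littorinimorpha	Calyptraeidae	Crucibulum
180195	Tamias minimus	species	true	Least Chipmunk|chipmunk	Animalia	Chordata	Mammalia	Rodentia	Sciuridae	Tamias
180137	Marmota flaviventris	species	true	Yellow-bellied Marmot|marmot	Animalia	Chordata	Mammalia	Rodentia	Sciuridae	Marmota
180112	Lepus americanus	species	true	Snowshoe Hare|hare	Animalia	Chordata	Mammalia	Lagomorpha	Leporidae	Lepus
180695	Cervus canadensis	species	true	elk|wapiti	Animalia	Chordata	Mammalia	Artiodactyla	Cervidae	Cervus
174999	Branta canadensis	species	true	Canada Goose|goose	Animalia	Chordata	Aves	Anseriformes	Anatidae	Branta
178041	Pipilo maculatus	species	true	Spotted Towhee|towhee	Animalia	Chordata	Aves	Passeriformes	Passerellidae	Pipilo
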