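genus	n_genomes
Caenorhabditis	22
Trichinella	12
Bursaphelenchus	10
Aphelenchoides	10
Haemonchus	6
Angiostrongylus	6
Teladorsagia	6
Ascaris	4
Toxocara	4
Heligmosomoides	4
Nippostrongylus	4
Dirofilaria	4
Trichuris	2
Steinernema	2
Meloidogyne	2
Diploscapter	2
Ancylostoma	2
Globodera	2
Heterodera	2
Panagrolaimus	2
Pristionchus	2
Strongyloides	2
Onchocerca	2
Brugia	2
Oesophagostomum	2
Romanomermis	1
Allodiplogaster	1
Parapristionchus	1
Plectus	1
Necator	1
Syphacia	1
Enterobius	1
Wuchereria	1
Loa	1
Elaeophora	1
Thelazia	1
Gongylonema	1
Dracunculus	1
Anisakis	1
Parascaris	1
Baylisascaris	1
Toxascaris	1
Oscheius	1
Mesorhabditis	1
Auanema	1
Halicephalobus	1
Acrobeloides	1
Ditylenchus	1
Anguina	1
Radopholus	1
Pratylenchus	1
Rotylenchulus	1
Tylenchulus	1
Xiphinema	1
Longidorus	1
Trichodorus	1
Soboliphyme	1
Dioctophyme	1
Hexamermis	1
Mermis	1
Thaumamermis	1
Ochoterenella	1
Setaria	1
Litomosoides	1
Acanthocheilonema	1
Mansonella	1
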