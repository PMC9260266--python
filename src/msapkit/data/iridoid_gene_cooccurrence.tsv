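taxon	DXS	DXR	10HGO	G10H	GPPS
Aquilegia coerulea	1	1	1	1	1
Citrus clementine	1	1	1	1	1
Citrus sinensis	1	1	1	1	1
Erythranthe guttata	1	1	1	1	1
Eucalyptus grandis	1	1	1	1	1
Gossypium raimondii	1	1	1	1	1
Malus domestica	1	1	1	1	1
Morus notabilis	1	1	1	1	1
Nelumbo nucifera	1	1	1	1	1
Nicotiana sylvestris	1	1	1	1	1
Nicotiana tomentosiformis	1	1	1	1	1
Populus trichocarpa	1	1	1	1	1
Prunus mume	1	1	1	1	1
Prunus persica	1	1	1	1	1
Pyrus x bretschneideri	1	1	1	1	1
Ricinus communis	1	1	1	1	1
Solanum lycopersicum	1	1	1	1	1
Theobroma cacao	1	1	1	1	1
Vitis vinifera	1	1	1	1	1
Cicer arietinum	1	1	1	0	1
Cucumis sativus	1	1	1	0	1
Fragaria vesca	1	1	1	0	1
Glycine max	1	1	1	0	1
Linum usitatissimum	1	1	1	0	1
Manihot esculenta	1	1	1	0	1
Phaseolus vulgaris	1	1	1	0	1
Beta vulgaris	1	1	0	1	1
Solanum tuberosum	1	1	1	1	0
Aegilops tauschii	1	1	0	0	1
Amborella trichopoda	1	1	0	0	1
Arabidopsis lyrata	1	1	0	0	1
Arabidopsis thaliana	1	1	0	0	1
Boechera stricta	1	1	0	0	1
Brachypodium distachyon	1	1	0	0	1
Brassica oleracea	1	1	0	0	1
Brassica rapa	1	1	0	0	1
Camelina sativa	1	1	0	0	1
Capsella grandiflora	1	1	0	0	1
Capsella rubella	1	1	0	0	1
Carica papaya	1	1	0	0	1
Cucumis melo	1	1	0	0	1
Eutrema salsugineum	1	1	0	0	1
Hordeum vulgare	1	1	0	0	1
Leersia perrieri	1	1	0	0	1
Musa acuminata	1	1	0	0	1
Oryza barthii	1	1	0	0	1
Oryza brachyantha	1	1	0	0	1
Oryza glaberrima	1	1	0	0	1
Oryza glumipatula	1	1	0	0	1
Oryza nivara	1	1	0	0	1
Oryza punctata	1	1	0	0	1
Oryza rufipogon	1	1	0	0	1
Oryza sativa	1	1	0	0	1
Panicum virgatum	1	1	0	0	1
Phoenix dactylifera	1	1	0	0	1
Physcomitrella patens	1	1	0	0	1
Selaginella moellendorffii	1	1	0	0	1
Setaria italic	1	1	0	0	1
Sorghum bicolor	1	1	0	0	1
Tarenaya hassleriana	1	1	0	0	1
Zea mays	1	1	0	0	1
Medicago truncatula	1	1	1	1	0
Arabis alpina	1	1	0	0	0
Triticum aestivum	0	1	0	0	1
Chlorella variabilis	0	1	0	0	0
Coccomyxa subellipsoidea	0	1	0	0	0
Triticum urartu	0	1	0	0	0
Volvox carteri	0	1	0	0	0
Micromonas pusilla	0	0	0	0	1
Oryza meridionalis	0	0	0	0	1
Ostreococcus lucimarinus	0	0	0	0	1
Ostreococcus tauri	0	0	0	0	1
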