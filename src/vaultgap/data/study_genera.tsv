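genus	status	attested
Triticum	retained	1
Oryza	retained	1
Hordeum	retained	1
Zea	retained	1
Sorghum	retained	1
Avena	retained	1
Pennisetum	retained	1
Setaria	retained	1
Aegilops	retained	1
Triticale	retained	1
Eleusine	retained	1
Amaranthus	retained	1
Secale	retained	1
Chenopodium	retained	1
Eragrostis	retained	1
Phaseolus	retained	1
Glycine	retained	1
Vigna	retained	1
Arachis	retained	1
Cicer	retained	1
Pisum	retained	1
Vicia	retained	1
Lens	retained	1
Cajanus	retained	1
Lupinus	retained	1
Psophocarpus	retained	1
Medicago	retained	1
Trifolium	retained	1
Panicum	retained	1
Solanum	retained	1
Ipomoea	retained	1
Brassica	retained	1
Capsicum	retained	1
Lycopersicon	retained	1
Cucumis	retained	1
Cucurbita	retained	1
Allium	retained	1
Sesamum	retained	1
Helianthus	retained	1
Carthamus	retained	1
Abelmoschus	retained	1
Gossypium	retained	1
Linum	retained	1
Saccharum	retained	1
Dactylis	retained	1
Festuca	retained	1
Agropyron	retained	0
Agrostis	retained	0
Alopecurus	retained	0
Althaea	retained	0
Anethum	retained	0
Apium	retained	0
Artemisia	retained	0
Asparagus	retained	0
Astragalus	retained	0
Atriplex	retained	0
Basella	retained	0
Benincasa	retained	0
Beta	retained	0
Brachiaria	retained	0
Bromus	retained	0
Calendula	retained	0
Camelina	retained	0
Canavalia	retained	0
Cannabis	retained	0
Carum	retained	0
Cenchrus	retained	0
Centrosema	retained	0
Chloris	retained	0
Cichorium	retained	0
Citrullus	retained	0
Coix	retained	0
Coriandrum	retained	0
Crambe	retained	0
Crotalaria	retained	0
Cuminum	retained	0
Cyamopsis	retained	0
Cynara	retained	0
Cynodon	retained	0
Daucus	retained	0
Desmodium	retained	0
Digitaria	retained	0
Echinochloa	retained	0
Elymus	retained	0
Eruca	retained	0
Fagopyrum	retained	0
Foeniculum	retained	0
Galega	retained	0
Guizotia	retained	0
Hedysarum	retained	0
Hibiscus	retained	0
Hypericum	retained	0
Indigofera	retained	0
Lablab	retained	0
Lactuca	retained	0
Lagenaria	retained	0
Lathyrus	retained	0
Lepidium	retained	0
Leucaena	retained	0
Lolium	retained	0
Lotus	retained	0
Luffa	retained	0
Macroptilium	retained	0
Macrotyloma	retained	0
Matricaria	retained	0
Melilotus	retained	0
Mentha	retained	0
Momordica	retained	0
Mucuna	retained	0
Nicotiana	retained	0
Nigella	retained	0
Ocimum	retained	0
Onobrychis	retained	0
Origanum	retained	0
Ornithopus	retained	0
Oryzopsis	retained	0
Papaver	retained	0
Paspalum	retained	0
Pastinaca	retained	0
Petroselinum	retained	0
Phalaris	retained	0
Phleum	retained	0
Physalis	retained	0
Pimpinella	retained	0
Plantago	retained	0
Poa	retained	0
Portulaca	retained	0
Puccinellia	retained	0
Raphanus	retained	0
Rheum	retained	0
Rhynchosia	retained	0
Ricinus	retained	0
Rumex	retained	0
Salvia	retained	0
Sanguisorba	retained	0
Scorzonera	retained	0
Sechium	retained	0
Sesbania	retained	0
Silybum	retained	0
Sinapis	retained	0
Spinacia	retained	0
Sporobolus	retained	0
Stipa	retained	0
Stylosanthes	retained	0
Tephrosia	retained	0
Tetragonia	retained	0
Thinopyrum	retained	0
Thymus	retained	0
Trichosanthes	retained	0
Trigonella	retained	0
Tripsacum	retained	0
Urochloa	retained	0
Valerianella	retained	0
Vetiveria	retained	0
Zizania	retained	0
Zoysia	retained	0
Amygdalis	excluded_not_in_vault	1
Anacardium	excluded_not_in_vault	1
Ananas	excluded_not_in_vault	1
Annona	excluded_not_in_vault	1
Bohemeria	excluded_not_in_vault	1
Carya	excluded_not_in_vault	1
Colocasia	excluded_not_in_vault	1
Dioscorea	excluded_not_in_vault	1
Ficus	excluded_not_in_vault	1
Gladiolus	excluded_not_in_vault	1
Ilex	excluded_not_in_vault	1
Jathropha	excluded_not_in_vault	1
Juglans	excluded_not_in_vault	1
Malus	excluded_not_in_vault	1
Manihot	excluded_not_in_vault	1
Morus	excluded_not_in_vault	1
Opuntia	excluded_not_in_vault	1
Oxalis	excluded_not_in_vault	1
Phoenix	excluded_not_in_vault	1
Pistacia	excluded_not_in_vault	1
Prunus	excluded_not_in_vault	1
Punica	excluded_not_in_vault	1
Tulipa	excluded_not_in_vault	1
Ullucus	excluded_not_in_vault	1
Vitis	excluded_not_in_vault	1
Zingiber	excluded_not_in_vault	1
Bactris	excluded_recalcitrant_intermediate	1
Camellia	excluded_recalcitrant_intermediate	1
Carica	excluded_recalcitrant_intermediate	1
Castanea	excluded_recalcitrant_intermediate	1
Cinnamonum	excluded_recalcitrant_intermediate	1
Citrus	excluded_recalcitrant_intermediate	1
Cocos	excluded_recalcitrant_intermediate	1
Coffea	excluded_recalcitrant_intermediate	1
Corylus	excluded_recalcitrant_intermediate	1
Curcuma	excluded_recalcitrant_intermediate	1
Durio	excluded_recalcitrant_intermediate	1
Elaeis	excluded_recalcitrant_intermediate	1
Garcinia	excluded_recalcitrant_intermediate	1
Hevea	excluded_recalcitrant_intermediate	1
Mangifera	excluded_recalcitrant_intermediate	1
Musa	excluded_recalcitrant_intermediate	1
Nephelium	excluded_recalcitrant_intermediate	1
Persea	excluded_recalcitrant_intermediate	1
Piper	excluded_recalcitrant_intermediate	1
Poncirus	excluded_recalcitrant_intermediate	1
Pouteria	excluded_recalcitrant_intermediate	1
Quercus	excluded_recalcitrant_intermediate	1
Salix	excluded_recalcitrant_intermediate	1
Theobroma	excluded_recalcitrant_intermediate	1
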