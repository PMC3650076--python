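genus,species,behavior
Triticum,aestivum,orthodox
Triticum,durum,orthodox
Oryza,sativa,orthodox
Oryza,glaberrima,orthodox
Zea,mays,orthodox
Hordeum,vulgare,orthodox
Phaseolus,vulgaris,orthodox
Glycine,max,orthodox
Solanum,tuberosum,orthodox
Solanum,lycopersicum,orthodox
Allium,cepa,orthodox
Brassica,oleracea,orthodox
Quercus,robur,recalcitrant
Quercus,ilex,recalcitrant
Camellia,sinensis,recalcitrant
Theobroma,cacao,recalcitrant
Cocos,nucifera,recalcitrant
Hevea,brasiliensis,recalcitrant
Persea,americana,recalcitrant
Mangifera,indica,recalcitrant
Castanea,sativa,recalcitrant
Coffea,arabica,intermediate
Coffea,canephora,intermediate
Citrus,limon,intermediate
Citrus,sinensis,intermediate
Elaeis,guineensis,intermediate
Musa,acuminata,intermediate
Carica,papaya,intermediate
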