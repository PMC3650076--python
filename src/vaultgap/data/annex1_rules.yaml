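# Curated genus-level encoding of the ITPGRFA Annex 1 crop list used by the
# coverage estimator. A genus with no rule here is treated as outside the
# Multilateral System (it can still be counted through Article 15 holdings).
# Species restrictions encode the best-known Annex 1 exceptions; the full
# species-level list used in published analyses is not public, so this file
# is an editable approximation that users can replace.
- crop: Wheat
  genera: [Triticum]
- crop: Rice
  genera: [Oryza]
- crop: Barley
  genera: [Hordeum]
- crop: Maize
  genera: [Zea]
  excluded_species: [perennis, diploperennis, luxurians]
- crop: Sorghum
  genera: [Sorghum]
- crop: Oat
  genera: [Avena]
- crop: Pearl Millet
  genera: [Pennisetum]
- crop: Finger Millet
  genera: [Eleusine]
- crop: Rye
  genera: [Secale]
- crop: Triticale
  genera: [Triticale]
- crop: Beans
  genera: [Phaseolus]
  excluded_species: [polyanthus]
- crop: Cowpea et al.
  genera: [Vigna]
- crop: Chickpea
  genera: [Cicer]
- crop: Pea
  genera: [Pisum]
- crop: Faba Bean / Vetch
  genera: [Vicia]
- crop: Lentil
  genera: [Lens]
- crop: Pigeon Pea
  genera: [Cajanus]
- crop: Potato
  genera: [Solanum]
  excluded_species: [phureja]
- crop: Sweet Potato
  genera: [Ipomoea]
- crop: Brassica complex
  genera: [Brassica, Raphanus, Sinapis]
- crop: Sunflower
  genera: [Helianthus]
- crop: Cassava
  genera: [Manihot]
  included_species: [esculenta]
- crop: Banana / Plantain
  genera: [Musa]
  excluded_species: [textilis]
- crop: Apple
  genera: [Malus]
- crop: Beet
  genera: [Beta]
- crop: Carrot
  genera: [Daucus]
- crop: Asparagus
  genera: [Asparagus]
- crop: Breadfruit
  genera: [Artocarpus]
  included_species: [altilis]
- crop: Forage legumes
  genera: [Astragalus, Canavalia, Hedysarum, Lathyrus, Lotus, Melilotus, Onobrychis, Ornithopus, Medicago, Trifolium]
- crop: Forage grasses
  genera: [Agropyron, Agrostis, Alopecurus, Dactylis, Festuca, Lolium, Phalaris, Phleum, Poa, Tripsacum]
- crop: Forage others
  genera: [Atriplex]
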