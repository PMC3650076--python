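genus	n_in_sgsv	n_under_sda
Oryza	4	5
Triticum	5	7
Hordeum	6	7
Sorghum	4	7
Zea	3	5
Glycine	4	6
Phaseolus	5	6
Vigna	4	7
Avena	5	7
Arachis	2	3
Cicer	6	7
Solanum	5	6
Pennisetum	3	4
Brassica	2	3
Vicia	5	5
Pisum	5	6
Setaria	4	5
Lens	5	7
Cajanus	3	7
Capsicum	3	5
Sesamum	1	5
Eleusine	4	5
Triticale	5	6
Cucumis	3	5
Helianthus	2	5
Lupinus	3	4
Ipomoea	3	3
Allium	3	5
Amaranthus	2	6
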