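genus	crop_group	wiews_total	genesys_total	wiews_distinct	wiews_itpgrfa	sgsv_total	annex1_listed
Triticum	Cereals	855639	367994	270237	599876	145698	1
Oryza	Cereals	773948	192983	440313	553235	145540	1
Hordeum	Cereals	469590	171603	138722	339448	61390	1
Zea	Cereals	323802	104518	134185	145921	32822	1
Sorghum	Cereals	235690	88801	75355	167769	40695	1
Avena	Cereals	131332	56489	24619	79349	11302	1
Pennisetum	Cereals	65447	24910	37024	89688	20444	1
Setaria	Cereals	46606	3193	5623	1675	2519	0
Aegilops	Cereals	42268	16238	19453	5173	3525	0
Triticale	Cereals	40470	2833	27587	31042	21455	1
Eleusine	Cereals	35382	7516	14602	38105	7636	1
Amaranthus	Cereals	28313	5620	14290	316	1300	0
Secale	Cereals	21452	15592	6091	13633	935	1
Chenopodium	Cereals	16263	1648	9028	34	111	0
Eragrostis	Cereals	8820	1760	6126	152	38	0
Phaseolus	Food Legumes	262491	96433	98890	246606	35230	1
Glycine	Food Legumes	230091	54797	74890	2102	17778	0
Vigna	Food Legumes	149590	48993	69302	91731	26129	1
Arachis	Food Legumes	128435	28489	31191	22857	14462	0
Cicer	Food Legumes	98319	48347	48432	115802	28872	1
Pisum	Food Legumes	95290	37258	20783	69193	9670	1
Vicia	Food Legumes	81470	36343	32632	75492	11573	1
Lens	Food Legumes	58430	19557	20589	56685	11946	1
Cajanus	Food Legumes	40820	13707	31702	53326	10076	1
Lupinus	Food Legumes	38053	13567	7503	183	591	0
Psophocarpus	Food Legumes	4217	454	1582	88	12	0
Medicago	Forage Crops	92019	27946	28413	9408	10912	1
Trifolium	Forage Crops	74707	34019	24062	6057	3944	1
Panicum	Forage Crops	48850	20448	12342	2273	2195	0
Solanum	Roots and Tubers	147566	58781	52180	48241	15733	1
Ipomoea	Roots and Tubers	35478	7927	16369	22864	1936	1
Brassica	Vegetables	101353	27889	26025	63624	7121	1
Capsicum	Vegetables	73520	21831	23945	1163	2163	0
Lycopersicon	Vegetables	59039	23863	10801	475	2866	0
Cucumis	Vegetables	44402	16674	8000	1	2428	0
Cucurbita	Vegetables	39599	14795	14411	2612	780	0
Allium	Vegetables	30064	12800	9816	0	630	0
Sesamum	Oil Crops	50462	3204	17946	1	1727	0
Helianthus	Oil Crops	39850	10921	5575	20509	1811	1
Carthamus	Oil Crops	29195	3494	6079	0	511	0
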