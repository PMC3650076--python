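genus	rank	holder	country	is_iarc	bracket_pct
Oryza	1	IRRI	PHL	1	107
Oryza	2	India	IND	0	0
Oryza	3	China	CHN	0	0
Oryza	4	China	CHN	0	0
Oryza	5	China	CHN	0	0
Oryza	6	Japan	JPN	0	0
Oryza	7	South Korea	KOR	0	4
Oryza	8	USA	USA	0	20
Oryza	9	WARDA	CIV	1	57
Triticum	1	CIMMYT	MEX	1	69
Triticum	2	USA	USA	0	17
Triticum	3	China	CHN	0	0
Triticum	4	India	IND	0	0
Triticum	5	ICARDA	SYR	1	95
Triticum	6	Japan	JPN	0	0
Triticum	7	Russia	RUS	0	3
Triticum	8	Italy	ITA	0	0
Triticum	9	Germany	DEU	0	5
Triticum	10	Australia	AUS	0	0
Hordeum	1	Canada	CAN	0	22
Hordeum	2	USA	USA	0	23
Hordeum	3	Brazil	BRA	0	0
Hordeum	4	ICARDA	SYR	1	97
Hordeum	5	Japan	JPN	0	0
Hordeum	6	Germany	DEU	0	11
Hordeum	7	China	CHN	0	0
Hordeum	8	South Korea	KOR	0	19
Hordeum	9	Russia	RUS	0	6
Hordeum	10	Ethiopia	ETH	0	0
Sorghum	1	ICRISAT	IND	1	83
Sorghum	2	USA	USA	0	13
Sorghum	3	USA	USA	0	62
Sorghum	4	China	CHN	0	0
Sorghum	5	India	IND	0	0
Sorghum	6	Ethiopia	ETH	0	0
Sorghum	7	Brazil	BRA	0	0
Sorghum	8	Kenya	KEN	0	10
Sorghum	9	Japan	JPN	0	0
Sorghum	10	Australia	AUS	0	0
Zea	1	CIMMYT	MEX	1	86
Zea	2	Portugal	PRT	0	0
Zea	3	USA	USA	0	4
Zea	4	China	CHN	0	0
Zea	5	Mexico	MEX	0	0
Zea	6	Mexico	MEX	0	0
Zea	7	Mexico	MEX	0	0
Zea	8	Mexico	MEX	0	0
Zea	9	Russia	RUS	0	10
Zea	10	India	IND	0	0
Glycine	1	China	CHN	0	0
Glycine	2	China	CHN	0	0
Glycine	3	China	CHN	0	0
Glycine	4	USA	USA	0	45
Glycine	5	South Korea	KOR	0	11
Glycine	6	AVRDC	TWN	1	0
Glycine	7	Brazil	BRA	0	0
Glycine	8	Brazil	BRA	0	0
Glycine	9	Japan	JPN	0	0
Glycine	10	Russia	RUS	0	0
Phaseolus	1	CIAT	COL	1	84
Phaseolus	2	USA	USA	0	5
Phaseolus	3	Brazil	BRA	0	0
Phaseolus	4	Brazil	BRA	0	0
Phaseolus	5	Brazil	BRA	0	0
Phaseolus	6	Mexico	MEX	0	0
Phaseolus	7	Mexico	MEX	0	0
Phaseolus	8	Germany	DEU	0	19
Phaseolus	9	China	CHN	0	0
Phaseolus	10	Russia	RUS	0	3
Vigna	1	IITA	NGA	1	74
Vigna	2	China	CHN	0	0
Vigna	3	USA	USA	0	1
Vigna	4	India	IND	0	0
Vigna	5	India	IND	0	0
Vigna	6	India	IND	0	0
Vigna	7	AVRDC	TWN	1	76
Vigna	8	Philippines	PHL	0	8
Vigna	9	Japan	JPN	0	0
Vigna	10	Brazil	BRA	0	0
Avena	1	Canada	CAN	0	13
Avena	2	Canada	CAN	0	0
Avena	3	USA	USA	0	26
Avena	4	Russia	RUS	0	2
Avena	5	Germany	DEU	0	7
Avena	6	Kenya	KEN	0	0
Avena	7	Australia	AUS	0	0
Avena	8	China	CHN	0	0
Avena	9	UK	GBR	0	0
Avena	10	Poland	POL	0	0
Arachis	1	ICRISAT	IND	1	58
Arachis	2	India	IND	0	0
Arachis	3	India	IND	0	0
Arachis	4	India	IND	0	0
Arachis	5	USA	USA	0	3
Arachis	6	Argentina	ARG	0	0
Arachis	7	Argentina	ARG	0	0
Arachis	8	Niger	NER	0	0
Arachis	9	China	CHN	0	0
Arachis	10	China	CHN	0	0
Cicer	1	ICRISAT	IND	1	85
Cicer	2	India	IND	0	0
Cicer	3	India	IND	0	0
Cicer	4	ICARDA	SYR	1	79
Cicer	5	Australia	AUS	0	0
Cicer	6	USA	USA	0	0
Cicer	7	Iran	IRN	0	0
Cicer	8	Pakistan	PAK	0	19
Cicer	9	Russia	RUS	0	3
Cicer	10	Turkey	TUR	0	0
Solanum	1	Russia	RUS	0	3
Solanum	2	AVRDC	TWN	1	18
Solanum	3	France	FRA	0	0
Solanum	4	CIP	PER	1	59
Solanum	5	USA	USA	0	98
Solanum	6	USA	USA	0	0
Solanum	7	USA	USA	0	0
Solanum	8	Germany	DEU	0	15
Solanum	9	India	IND	0	0
Solanum	10	Japan	JPN	0	0
Pennisetum	1	ICRISAT	IND	1	88
Pennisetum	2	Brazil	BRA	0	0
Pennisetum	3	India	IND	0	0
Pennisetum	4	India	IND	0	0
Pennisetum	5	France	FRA	0	0
Pennisetum	6	Canada	CAN	0	0
Pennisetum	7	India	IND	0	0
Pennisetum	8	Niger	NER	0	0
Pennisetum	9	Uganda	UGA	0	0
Pennisetum	10	USA	USA	0	13
Brassica	1	India	IND	0	0
Brassica	2	India	IND	0	0
Brassica	3	India	IND	0	0
Brassica	4	India	IND	0	0
Brassica	5	China	CHN	0	0
Brassica	6	China	CHN	0	0
Brassica	7	Australia	AUS	0	0
Brassica	8	Japan	JPN	0	0
Brassica	9	Russia	RUS	0	3
Brassica	10	UK	GBR	0	0
Vicia	1	ICARDA	SYR	1	63
Vicia	2	Russia	RUS	0	3
Vicia	3	Australia	AUS	0	0
Vicia	4	Germany	DEU	0	14
Vicia	5	China	CHN	0	0
Vicia	6	Italy	ITA	0	0
Vicia	7	Spain	ESP	0	0
Vicia	8	USA	USA	0	11
Vicia	9	Turkey	TUR	0	0
Vicia	10	Bulgaria	BGR	0	0
Pisum	1	Australia	AUS	0	4
Pisum	2	Russia	RUS	0	1
Pisum	3	ICARDA	SYR	1	62
Pisum	4	Germany	DEU	0	16
Pisum	5	USA	USA	0	28
Pisum	6	Italy	ITA	0	0
Pisum	7	China	CHN	0	0
Pisum	8	UK	GBR	0	0
Pisum	9	UK	GBR	0	0
Pisum	10	India	IND	0	0
Setaria	1	China	CHN	0	0
Setaria	2	India	IND	0	0
Setaria	3	France	FRA	0	0
Setaria	4	France	FRA	0	0
Setaria	5	Japan	JPN	0	0
Setaria	6	ICRISAT	IND	1	92
Setaria	7	USA	USA	0	71
Setaria	8	Kenya	KEN	0	0
Setaria	9	UK	GBR	0	0
Lens	1	ICARDA	SYR	1	99
Lens	2	India	IND	0	0
Lens	3	India	IND	0	0
Lens	4	Australia	AUS	0	0
Lens	5	Iran	IRN	0	0
Lens	6	USA	USA	0	0
Lens	7	Russia	RUS	0	6
Lens	8	Chile	CHL	0	0
Lens	9	Canada	CAN	0	32
Lens	10	Hungary	HUN	0	0
Cajanus	1	ICRISAT	IND	1	73
Cajanus	2	India	IND	0	0
Cajanus	3	India	IND	0	0
Cajanus	4	India	IND	0	0
Cajanus	5	India	IND	0	0
Cajanus	6	Kenya	KEN	0	4
Cajanus	7	Philippines	PHL	0	3
Cajanus	8	Australia	AUS	0	0
Cajanus	9	Brazil	BRA	0	0
Cajanus	10	Nepal	NPL	0	0
Capsicum	1	AVRDC	TWN	1	4
Capsicum	2	USA	USA	0	5
Capsicum	3	Mexico	MEX	0	0
Capsicum	4	Mexico	MEX	0	0
Capsicum	5	Mexico	MEX	0	0
Capsicum	6	India	IND	0	0
Capsicum	7	Brazil	BRA	0	0
Capsicum	8	Brazil	BRA	0	0
Capsicum	9	Japan	JPN	0	0
Capsicum	10	Philippines	PHL	0	0
Sesamum	1	India	IND	0	0
Sesamum	2	India	IND	0	0
Sesamum	3	India	IND	0	0
Sesamum	4	China	CHN	0	0
Sesamum	5	China	CHN	0	0
Sesamum	6	Israel	ISR	0	0
Sesamum	7	Kenya	KEN	0	0
Sesamum	8	Brazil	BRA	0	0
Sesamum	9	Japan	JPN	0	0
Sesamum	10	Mexico	MEX	0	0
Eleusine	1	India	IND	0	0
Eleusine	2	India	IND	0	0
Eleusine	3	India	IND	0	0
Eleusine	4	ICRISAT	IND	1	98
Eleusine	5	Kenya	KEN	0	19
Eleusine	6	Ethiopia	ETH	0	0
Eleusine	7	Uganda	UGA	0	0
Eleusine	8	Zambia	ZMB	0	3
Eleusine	9	Nepal	NPL	0	0
Eleusine	10	USA	USA	0	88
Triticale	1	CIMMYT	MEX	1	114
Triticale	2	Russia	RUS	0	0
Triticale	3	USA	USA	0	5
Triticale	4	Canada	CAN	0	5
Triticale	5	Ukraine	UKR	0	0
Triticale	6	Poland	POL	0	0
Triticale	7	Germany	DEU	0	7
Triticale	8	Bulgaria	BGR	0	0
Triticale	9	Slovakia	SVK	0	0
Triticale	10	Uzbekistan	UZB	0	0
Cucumis	1	USA	USA	0	23
Cucumis	2	Japan	JPN	0	0
Cucumis	3	Russia	RUS	0	0
Cucumis	4	China	CHN	0	0
Cucumis	5	China	CHN	0	0
Cucumis	6	Brazil	BRA	0	0
Cucumis	7	Kazakhstan	KAZ	0	0
Cucumis	8	France	FRA	0	0
Cucumis	9	Germany	DEU	0	22
Cucumis	10	India	IND	0	0
Helianthus	1	Serbia	SRB	0	0
Helianthus	2	USA	USA	0	37
Helianthus	3	China	CHN	0	0
Helianthus	4	France	FRA	0	0
Helianthus	5	Brazil	BRA	0	0
Helianthus	6	Brazil	BRA	0	0
Helianthus	7	Russia	RUS	0	0
Helianthus	8	Australia	AUS	0	0
Helianthus	9	India	IND	0	0
Helianthus	10	Morocco	MAR	0	0
Lupinus	1	Australia	AUS	0	0
Lupinus	2	Australia	AUS	0	0
Lupinus	3	Germany	DEU	0	6
Lupinus	4	Russia	RUS	0	1
Lupinus	5	France	FRA	0	0
Lupinus	6	Peru	PER	0	0
Lupinus	7	Peru	PER	0	0
Lupinus	8	Peru	PER	0	0
Lupinus	9	Spain	ESP	0	0
Lupinus	10	UK	GBR	0	0
Ipomoea	1	CIP	PER	1	30
Ipomoea	2	Japan	JPN	0	0
Ipomoea	3	Japan	JPN	0	0
Ipomoea	4	Japan	JPN	0	0
Ipomoea	5	USA	USA	0	0
Ipomoea	6	Papua New Guinea	PNG	0	0
Ipomoea	7	Brazil	BRA	0	0
Ipomoea	8	China	CHN	0	0
Ipomoea	9	Taiwan ROC	TWN	0	0
Allium	1	India	IND	0	0
Allium	2	Russia	RUS	0	0
Allium	3	Japan	JPN	0	0
Allium	4	USA	USA	0	0
Allium	5	USA	USA	0	0
Allium	6	Germany	DEU	0	12
Allium	7	AVRDC	TWN	1	0
Allium	8	UK	GBR	0	0
Allium	9	UK	GBR	0	0
Allium	10	Hungary	HUN	0	0
Amaranthus	1	India	IND	0	0
Amaranthus	2	India	IND	0	0
Amaranthus	3	India	IND	0	0
Amaranthus	4	USA	USA	0	29
Amaranthus	5	Brazil	BRA	0	0
Amaranthus	6	Peru	PER	0	0
Amaranthus	7	China	CHN	0	0
Amaranthus	8	Hungary	HUN	0	0
Amaranthus	9	AVRDC	TWN	1	33
Amaranthus	10	Argentina	ARG	0	0
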