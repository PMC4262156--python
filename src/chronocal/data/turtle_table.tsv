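node_id	near_id	node_label	fossil	min_post	max_post	near	marshall	dornburg	apriori_assessment	min_priori	max_priori	attached
1.0	1.0	Testudines	Proterochersis robusta	210.0		consistent		omitted	phyl. misplaced	155.6	251.4	True
2.0	3.0	Pleurodira	Araripemys barretoi	110.0	134.4	consistent		consistent	accurate minima	111.0	165.2	True
3.0	4.0	Pelomedusoides	Cearachelys placidoi	110.0	134.4	consistent		consistent	accurate minima	92.8	149.5	True
4.0	14.0	Pelomedusidae	Pelusios rusingae	18.0	22.0	consistent		inconsistent	inaccurately dated	5.3	149.5	True
5.0	11.0	Chelidae	Yaminuechelys gasparinii	71.0	86.7	inconsistent		consistent	accurate minima	65.2	149.5	True
6.0	15.0	Chelodininae	Chelodina sp., Elseya sp.	15.0	18.3	inconsistent		inconsistent	accurate minima	11.6	149.5	True
7.0	16.0	Chelus_Phrynops	Chelus sp.	11.6	14.2	inconsistent		inconsistent	accurate minima	13.4	149.5	True
8.0	2.0	Cryptodira	Sandownia harrisi	110.0		consistent		omitted	phyl. misplaced	124.0	200.2	True
9.0	18.0	Trionychia								124.0	177.6	True
10.0	6.0	Trionychidae	Aspideretes maortuensis	100.0	122.1	consistent	selected	consistent	phyl. untested	17.3	149.5	True
11.0	19.0	Durocryptodira								88.6	149.5	True
12.0	20.0	Americhelydia								70.0	149.5	True
13.0	5.0	Chelonioidea	Santanachelys gaffneyi	110.0	134.3	inconsistent	inconsistent	consistent/inconsistent	phyl. misplaced	48.4	149.5	True
14.0	21.0	Chelydroidea								70.0	149.5	True
15.0	7.0	Kinosternoidea	Hoplochelys sp.	65.0	79.4	consistent		consistent	accurate minima	70.0	149.5	True
16.0	10.0	Kinosternidae	Baltemys sp.	50.0	61.1	consistent		consistent	accurate minima	52.8	149.5	True
17.0		Testudinoidea								50.3	149.5	True
18.0		Emydidae_Platysternon								32.0	100.5	True
19.0	12.0	Emydidae	Chrysemys antiqua	34.0	41.5	consistent		consistent	accurate minima	32.0	100.5	True
20.0	17.0	Graptemys_Trachemys	Trachemys inflata	5.0	6.1	inconsistent		inconsistent	phyl. untested	3.0	34.0	True
21.0	8.0	Testuguria	Hadrianus majusculus	52.0	63.5	consistent		consistent	accurate minima	50.3	100.5	True
22.0	9.0	Heosemys_Mauremys	Ocadia crassa	50.0	61.1	inconsistent		consistent	phyl. untested	5.3	65.8	True
	13.0	Lindholmemydidae		90.0	109.9	consistent		consistent	phyl. untested			False
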