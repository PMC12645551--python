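study_id	variable	group	day	value	kind
jones_pickering	pituitary_VP	SL	1	78	obs
jones_pickering	pituitary_VP	SL	2	51	obs
jones_pickering	pituitary_VP	SL	3	32	obs
jones_pickering	pituitary_VP	SL	5	18	obs
jones_pickering	pituitary_VP	SL		18	printed_av
jones_pickering	pituitary_OT	SL	1	71	obs
jones_pickering	pituitary_OT	SL	2	29	obs
jones_pickering	pituitary_OT	SL	3	20	obs
jones_pickering	pituitary_OT	SL	5	10	obs
jones_pickering	pituitary_OT	SL		10	printed_av
dyball_pountney	pituitary_VP	SL	3	33	obs
dyball_pountney	pituitary_OT	SL	3	29	obs
bakker_dyball	pituitary_VP	SL	1	95	obs
bakker_dyball	pituitary_VP	SL	3	48	obs
bakker_dyball	pituitary_OT	SL	1	85	obs
bakker_dyball	pituitary_OT	SL	3	36	obs
george	pituitary_VP	SL	3	46	obs
hollt	pituitary_VP	SL	5	5	obs
hollt	pituitary_VP	SL		5	printed_av
zingg_1986	pituitary_VP	SL	1	77	obs
zingg_1986	pituitary_VP	SL	2	58	obs
zingg_1986	pituitary_VP	SL	6	17	obs
zingg_1986	pituitary_VP	SL		17	printed_av
hooi	pituitary_VP	SL	2	13	obs
hooi	pituitary_VP	SL	7	7	obs
hooi	pituitary_VP	SL		7	printed_av
higuchi	pituitary_VP	SL	2	61	obs
higuchi	pituitary_VP	SL	4	32	obs
higuchi	pituitary_OT	SL	2	62	obs
higuchi	pituitary_OT	SL	4	51	obs
crowley_amico_a	pituitary_VP	SL	5	15	obs
crowley_amico_a	pituitary_OT	SL	5	21	obs
crowley_amico_b	pituitary_VP	SL	5	37	obs
crowley_amico_b	pituitary_OT	SL	5	17	obs
crowley_amico	pituitary_VP	SL		26	printed_av
crowley_amico	pituitary_OT	SL		19	printed_av
kadowaki	pituitary_VP	SL	3	43	obs
kadowaki	pituitary_VP	SL	4	42	obs
kadowaki	pituitary_OT	SL	3	38	obs
kadowaki	pituitary_OT	SL	4	25	obs
sheikh	pituitary_VP	SL	2	64	obs
sheikh	pituitary_VP	SL	7	18	obs
sheikh	pituitary_VP	SL		18	printed_av
morita	pituitary_VP	SL	7	5	obs
morita	pituitary_VP	SL		5	printed_av
bojanowska_stempniak	pituitary_VP	SL	6	37	obs
bojanowska_stempniak	pituitary_VP	SL		37	printed_av
bojanowska_stempniak	pituitary_OT	SL	6	51	obs
bojanowska_stempniak	pituitary_OT	SL		51	printed_av
kondo	pituitary_VP	SL	12	18	obs
summy_long	pituitary_VP	SL	2	39	obs
summy_long	pituitary_VP	SL	5	31	obs
summy_long	pituitary_VP	SL	8	15	obs
summy_long	pituitary_VP	SL		23	printed_av
summy_long	pituitary_OT	SL	2	95	obs
summy_long	pituitary_OT	SL	5	41	obs
summy_long	pituitary_OT	SL	8	21	obs
summy_long	pituitary_OT	SL		31	printed_av
yue	pituitary_VP	SL	1	73	obs
yue	pituitary_VP	SL	2	65	obs
yue	pituitary_VP	SL	3	44	obs
yue	pituitary_VP	SL	5	20	obs
yue	pituitary_VP	SL		20	printed_av
yue	pituitary_OT	SL	1	44	obs
yue	pituitary_OT	SL	2	42	obs
yue	pituitary_OT	SL	3	22	obs
yue	pituitary_OT	SL	5	10	obs
yue	pituitary_OT	SL		10	printed_av
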