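study_id	variable	group	day	value	kind
jones_pickering	haematocrit	EU		43	obs
jones_pickering	haematocrit	SL	1	47	obs
jones_pickering	haematocrit	SL	2	46	obs
jones_pickering	haematocrit	SL	3	48.5	obs
jones_pickering	haematocrit	SL	5	47	obs
jones_pickering	haematocrit	SL		47.1	printed_av
jones_pickering	haematocrit_delta	SL		4.1	printed_delta
lepetit	haematocrit	EU		43	obs
lepetit	haematocrit	SL	3	47	obs
lepetit	haematocrit	SL		47	printed_av
lepetit	haematocrit_delta	SL		4	printed_delta
yagita	haematocrit	EU		41.2	obs
yagita	haematocrit	SL	7	49.2	obs
yagita	haematocrit	SL		49.2	printed_av
yagita	haematocrit_delta	SL		8	printed_delta
callahan	haematocrit	EU		42	obs
callahan	haematocrit	SL	4	39	obs
callahan	haematocrit	SL		39	printed_av
callahan	haematocrit_delta	SL		-3	printed_delta
li	haematocrit	EU		42	obs
li	haematocrit	SL	4	41	obs
li	haematocrit	SL		41	printed_av
li	haematocrit_delta	SL		-1	printed_delta
morita	haematocrit	EU		40.5	obs
morita	haematocrit	SL	7	48.3	obs
morita	haematocrit	SL		48.3	printed_av
morita	haematocrit_delta	SL		7.8	printed_delta
bojanowska_stempniak	haematocrit	EU		42	obs
bojanowska_stempniak	haematocrit	SL	6	46	obs
bojanowska_stempniak	haematocrit	SL		46	printed_av
bojanowska_stempniak	haematocrit_delta	SL		4	printed_delta
somponpun_sladek	haematocrit	EU		41.2	obs
somponpun_sladek	haematocrit	SL	3	45.1	obs
somponpun_sladek	haematocrit	SL		45.1	printed_av
somponpun_sladek	haematocrit_delta	SL		3.9	printed_delta
summy_long	haematocrit	EU		44.7	obs
summy_long	haematocrit	SL	2	45.1	obs
summy_long	haematocrit	SL	5	43	obs
summy_long	haematocrit	SL	8	44.5	obs
summy_long	haematocrit	SL		43.75	printed_av
summy_long	haematocrit_delta	SL		-0.95	printed_delta
balapattabi_2019	haematocrit	EU		42.6	obs
balapattabi_2019	haematocrit	SL	7	47.8	obs
balapattabi_2019	haematocrit	SL		47.8	printed_av
balapattabi_2019	haematocrit_delta	SL		5.2	printed_delta
balapattabi_2018	haematocrit	EU		42.5	obs
balapattabi_2018	haematocrit	SL	7	47	obs
balapattabi_2018	haematocrit	SL		47	printed_av
balapattabi_2018	haematocrit_delta	SL		4.5	printed_delta
ribeiro_2015	haematocrit	EU		43.8	obs
ribeiro_2015	haematocrit	SL	7	46.4	obs
ribeiro_2015	haematocrit	SL		46.4	printed_av
ribeiro_2015	haematocrit_delta	SL		2.6	printed_delta
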