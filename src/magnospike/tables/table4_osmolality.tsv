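study_id	variable	group	day	value	kind
jones_pickering	osmolality	EU		314	obs
jones_pickering	osmolality	SL	1	321	obs
jones_pickering	osmolality	SL	2	314	obs
jones_pickering	osmolality	SL	3	346	obs
jones_pickering	osmolality	SL	5	336	obs
jones_pickering	osmolality	SL	6	307	obs
zingg_1986	osmolality	EU		290	obs
zingg_1986	osmolality	SL	1	296	obs
zingg_1986	osmolality	SL	2	295	obs
carter_lightman	osmolality	EU		291	obs
carter_lightman	osmolality	SL	1	297	obs
carter_lightman	osmolality	SL	2	301	obs
carter_lightman	osmolality	SL	3	305	obs
carter_lightman	osmolality	SL	4	314	obs
carter_lightman	osmolality	SL	5	307	obs
carter_lightman	osmolality	SL	6	315	obs
carter_lightman	osmolality	SL	7	322	obs
carter_lightman	osmolality_delta	SL	7	31	printed_delta
zingg_1988	osmolality	EU		290	obs
zingg_1988	osmolality	SL	6	312	obs
hyodo_urano	osmolality	EU		289	obs
hyodo_urano	osmolality	SL	2	305	obs
hyodo_urano	osmolality	SL	4	309	obs
hyodo_urano	osmolality	SL	7	322	obs
hyodo_urano	osmolality_delta	SL	7	33	printed_delta
carter_murphy	osmolality	EU		288	obs
carter_murphy	osmolality	SL	3	308	obs
hooi	osmolality	EU		308	obs
hooi	osmolality	SL	2	331	obs
hooi	osmolality	SL	3	319	obs
hooi	osmolality	SL	7	362	obs
hooi	osmolality_delta	SL	7	54	printed_delta
lafarga	osmolality	EU		294	obs
lafarga	osmolality	SL	1	319	obs
lepetit	osmolality	EU		297	obs
lepetit	osmolality	SL	3	319	obs
miyata	osmolality	EU		295	obs
miyata	osmolality	SL	1	303	obs
miyata	osmolality	SL	3	313	obs
miyata	osmolality	SL	5	335	obs
miyata	osmolality	SL	7	375	obs
miyata	osmolality_delta	SL	7	80	printed_delta
yagita	osmolality	EU		308	obs
yagita	osmolality	SL	7	343	obs
yagita	osmolality_delta	SL	7	35	printed_delta
dai_yao_a	osmolality	EU		290	obs
dai_yao_a	osmolality	SL	4	304	obs
dai_yao_b	osmolality	EU		282	obs
dai_yao_b	osmolality	SL	4	352	obs
li	osmolality	EU		310	obs
li	osmolality	SL	4	320	obs
curras_collazo_dao	osmolality	EU		296	obs
curras_collazo_dao	osmolality	SL	3	325	obs
curras_collazo_dao	osmolality	SL	4	330	obs
curras_collazo_dao	osmolality	SL	7	330	obs
curras_collazo_dao	osmolality_delta	SL	7	34	printed_delta
glasgow	osmolality	EU		302	obs
glasgow	osmolality	SL	7	317	obs
glasgow	osmolality_delta	SL	7	15	printed_delta
zemo_mccabe	osmolality	EU		263	obs
zemo_mccabe	osmolality	SL	7	292	obs
zemo_mccabe	osmolality_delta	SL	7	28.6	printed_delta
morita	osmolality	EU		280	obs
morita	osmolality	SL	7	344	obs
morita	osmolality_delta	SL	7	64	printed_delta
zhang	osmolality	EU		291	obs
zhang	osmolality	SL	7	312	obs
zhang	osmolality_delta	SL	7	21	printed_delta
saito	osmolality	EU		293	obs
saito	osmolality	SL	7	378	obs
saito	osmolality_delta	SL	7	85	printed_delta
somponpun_sladek	osmolality	EU		296	obs
somponpun_sladek	osmolality	SL	3	313	obs
bojanowska_stempniak	osmolality	EU		279	obs
bojanowska_stempniak	osmolality	SL	6	314	obs
ventura	osmolality	EU		299	obs
ventura	osmolality	SL	1	308	obs
summy_long	osmolality	EU		295	obs
summy_long	osmolality	SL	2	297	obs
summy_long	osmolality	SL	5	299	obs
yue	osmolality	EU		291	obs
yue	osmolality	SL	1	301	obs
yue	osmolality	SL	2	308	obs
yue	osmolality	SL	3	313	obs
yue	osmolality	SL	5	326	obs
kim	osmolality	EU		306	obs
kim	osmolality	SL	1	331	obs
kim	osmolality	SL	7	359	obs
kim	osmolality_delta	SL	7	53	printed_delta
doherty_sladek	osmolality	EU		301	obs
doherty_sladek	osmolality	SL	3	308	obs
choe	osmolality	EU		301	obs
choe	osmolality	SL	7	350	obs
choe	osmolality_delta	SL	7	49	printed_delta
greenwood	osmolality	EU		298	obs
greenwood	osmolality	SL	7	326	obs
greenwood	osmolality_delta	SL	7	28	printed_delta
ribeiro_a	osmolality	EU		295	obs
ribeiro_a	osmolality	SL	4	333	obs
mucio_ramirez	osmolality	EU		297	obs
mucio_ramirez	osmolality	SL	5	321	obs
balapattabi_2019	osmolality	EU		301	obs
balapattabi_2019	osmolality	SL	7	313	obs
balapattabi_2019	osmolality_delta	SL	7	12	printed_delta
balapattabi_2018	osmolality	EU		299	obs
balapattabi_2018	osmolality	SL	7	309	obs
balapattabi_2018	osmolality_delta	SL	7	9.8	printed_delta
di	osmolality	EU		295	obs
di	osmolality	SL	6	353	obs
di	osmolality	SL	7	329	obs
di	osmolality_delta	SL	7	34	printed_delta
ribeiro_b	osmolality	EU		294	obs
ribeiro_b	osmolality	SL	7	308	obs
ribeiro_b	osmolality_delta	SL	7	14	printed_delta
barad	osmolality	EU		299	obs
barad	osmolality	SL	7	382	obs
barad	osmolality_delta	SL	7	83	printed_delta
neupane	osmolality	EU		308	obs
neupane	osmolality	SL	1	330	obs
neupane	osmolality	SL	7	361	obs
neupane	osmolality_delta	SL	7	53	printed_delta
levi	osmolality	EU		299	obs
levi	osmolality	SL	7	339	obs
levi	osmolality_delta	SL	7	40	printed_delta
gomes	osmolality	EU		288	obs
gomes	osmolality	SL	7	290	obs
gomes	osmolality_delta	SL	7	2	printed_delta
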