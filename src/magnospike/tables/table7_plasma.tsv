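study_id	variable	group	day	value	kind
mens	plasma_VP	EU		1.4	obs
mens	plasma_VP	SL	1	15	obs
mens	plasma_VP	SL	2	17.7	obs
mens	plasma_VP	SL	3	14.7	obs
mens	plasma_VP	SL		14.7	printed_av
carter_lightman	plasma_VP	EU		3.4	obs
carter_lightman	plasma_OT	EU		6.1	obs
carter_lightman	plasma_VP	SL	1	7.1	obs
carter_lightman	plasma_VP	SL	2	15.3	obs
carter_lightman	plasma_VP	SL	3	12.3	obs
carter_lightman	plasma_VP	SL	4	10	obs
carter_lightman	plasma_VP	SL	5	10.4	obs
carter_lightman	plasma_VP	SL	6	20.4	obs
carter_lightman	plasma_VP	SL	7	13.7	obs
carter_lightman	plasma_VP	SL	9	10	obs
carter_lightman	plasma_VP	SL		12.8	printed_av
carter_lightman	plasma_OT	SL	1	8	obs
carter_lightman	plasma_OT	SL	2	13.3	obs
carter_lightman	plasma_OT	SL	3	11.1	obs
carter_lightman	plasma_OT	SL	4	12.9	obs
carter_lightman	plasma_OT	SL	5	12.2	obs
carter_lightman	plasma_OT	SL	6	14.7	obs
carter_lightman	plasma_OT	SL	7	11.4	obs
carter_lightman	plasma_OT	SL	9	13.6	obs
carter_lightman	plasma_OT	SL		12.7	printed_av
van_tol	plasma_VP	EU		0.6	obs
van_tol	plasma_OT	EU		2	obs
van_tol	plasma_VP	SL	14	5.2	obs
van_tol	plasma_VP	SL		5.2	printed_av
van_tol	plasma_OT	SL	14	3.5	obs
van_tol	plasma_OT	SL		3.5	printed_av
hooi	plasma_VP	EU		2	obs
hooi	plasma_VP	SL	2	5.2	obs
hooi	plasma_VP	SL	7	4.1	obs
hooi	plasma_VP	SL		4.1	printed_av
blackburn	plasma_VP	EU		4.3	obs
blackburn	plasma_OT	EU		9.8	obs
blackburn	plasma_VP	SL	2	10.4	obs
blackburn	plasma_OT	SL	2	17.9	obs
callahan	plasma_VP	EU		1.8	obs
callahan	plasma_VP	SL	4	2.4	obs
callahan	plasma_VP	SL		2.4	printed_av
li	plasma_VP	EU		0.3	obs
li	plasma_VP	SL	4	1.7	obs
li	plasma_VP	SL		1.7	printed_av
morita	plasma_VP	EU		0.9	obs
morita	plasma_VP	SL	7	6	obs
morita	plasma_VP	SL		6	printed_av
bojanowska_stempniak	plasma_VP	EU		4.1	obs
bojanowska_stempniak	plasma_OT	EU		1.7	obs
bojanowska_stempniak	plasma_VP	SL	6	21.7	obs
bojanowska_stempniak	plasma_VP	SL		21.7	printed_av
bojanowska_stempniak	plasma_OT	SL	6	18.8	obs
bojanowska_stempniak	plasma_OT	SL		18.8	printed_av
somponpun_sladek	plasma_VP	EU		1	obs
somponpun_sladek	plasma_OT	EU		15.7	obs
somponpun_sladek	plasma_VP	SL	3	4.2	obs
somponpun_sladek	plasma_VP	SL		4.2	printed_av
somponpun_sladek	plasma_OT	SL	3	25.5	obs
somponpun_sladek	plasma_OT	SL		25.5	printed_av
cisowska_ciosek	plasma_VP	EU		4.4	obs
cisowska_ciosek	plasma_OT	EU		3.2	obs
cisowska_ciosek	plasma_VP	SL	2	6.7	obs
cisowska_ciosek	plasma_OT	SL	2	4.3	obs
ventura	plasma_VP	EU		2.8	obs
ventura	plasma_OT	EU		4.7	obs
ventura	plasma_VP	SL	1	4.7	obs
ventura	plasma_VP	SL	7	5.6	obs
ventura	plasma_VP	SL		5.6	printed_av
ventura	plasma_OT	SL	1	17.3	obs
ventura	plasma_OT	SL	7	8.5	obs
ventura	plasma_OT	SL		8.5	printed_av
summy_long	plasma_VP	EU		1.6	obs
summy_long	plasma_OT	EU		5.3	obs
summy_long	plasma_VP	SL	2	2.9	obs
summy_long	plasma_VP	SL	5	1.9	obs
summy_long	plasma_VP	SL	8	2.9	obs
summy_long	plasma_VP	SL		2.4	printed_av
summy_long	plasma_OT	SL	2	5.5	obs
summy_long	plasma_OT	SL	5	9.2	obs
summy_long	plasma_OT	SL	8	6.5	obs
summy_long	plasma_OT	SL		7.9	printed_av
yue	plasma_VP	EU		1	obs
yue	plasma_OT	EU		4.7	obs
yue	plasma_VP	SL	1	3.2	obs
yue	plasma_VP	SL	2	3.8	obs
yue	plasma_VP	SL	3	3.4	obs
yue	plasma_VP	SL	5	4.1	obs
yue	plasma_VP	SL		3.8	printed_av
yue	plasma_OT	SL	1	14.3	obs
yue	plasma_OT	SL	2	16	obs
yue	plasma_OT	SL	3	6.5	obs
yue	plasma_OT	SL	5	8	obs
yue	plasma_OT	SL		11.2	printed_av
greenwood	plasma_VP	EU		1.1	obs
greenwood	plasma_OT	EU		0.8	obs
greenwood	plasma_VP	SL	7	6.4	obs
greenwood	plasma_VP	SL		6.4	printed_av
greenwood	plasma_OT	SL	7	2.1	obs
greenwood	plasma_OT	SL		2.1	printed_av
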