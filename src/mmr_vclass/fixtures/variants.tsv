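variant_id	family_id	gene	hgvs_c	hgvs_p	variant_type	clinvar_id	gnomad_af	prior_probability	spliceai_delta	functional_evidence	nmd_predicted
V01	F_051	MLH1	c.71_85del	p.(Val24_Pro28del)	inframe_deletion	NA	0	NA	0.02	none	NA
V02	F_161	MLH1	c.539_541del	p.(Val180del)	inframe_deletion	185186	0	NA	0.01	none	NA
V03	F_161	MSH6	c.4068_4071dup	p.(Lys1358Aspfs*2)	frameshift	89518	NA	NA	0.1	none	false
V04	F_176	MLH1	c.1594G>C	p.(Gly532Arg)	missense	NA	0	0.96	0.01	none	NA
V05	F_326	MLH1	c.1595G>A	p.(Gly532Asp)	missense	976474	0	0.96	0.01	none	NA
V06	F_376	MSH2	exon 1-6 duplication	p.?	exon_duplication	NA	0	NA	NA	none	false
V07	F_058	MSH2	exon 1-6 duplication	p.?	exon_duplication	NA	0	NA	NA	none	false
V08	F_149	MSH2	exon 14-15 duplication	p.?	exon_duplication	NA	0	NA	NA	none	true
V09	F_138	MSH2	c.328A>C	p.(Lys110Gln)	missense	127642	0.00000398	0.06	0.01	none	NA
V10	F_315	MSH2	c.1862G>T	p.(Arg621Leu)	missense	218040	0.0000319	0.85	0	none	NA
V11	F_008	MSH2	c.2005+3_2005+14del	p.?	splice	90842	0	0.26	0.57	none	NA
V12	F_132	MSH2	c.2060T>C	p.(Leu687Pro)	missense	90873	0	0.96	0	none	NA
V13	F_156	MSH6	c.3556+5_3556+8delins	p.?	splice	NA	0	0.26	0	none	NA
V14	F_143	PMS2	c.137G>T	p.(Ser46Ile)	missense	9245	0.000163	0.939	0.03	none	NA
V15	F_328	MLH1	c.1153C>T	p.(Arg385Cys)	missense	89653	0.0000597	0.937	0.03	none	NA
V16	F_202	MSH2	c.138C>G	p.(His46Gln)	missense	90654	0.000218	0.74	0	none	NA
V17	F_395	MSH2	c.668T>C	p.(Leu223Pro)	missense	408456	0	0.525	0	none	NA
V18	F_089	MSH6	c.2827G>T	p.(Asp943Tyr)	missense	142495	0.000046	0.05	0	none	NA
V19	F_046	MSH6	c.2950A>C	p.(Asn984His)	missense	186492	0.0000479	0.005	0	none	NA
V20	F_263	MSH6	c.*85T>A	p.?	utr3	89155	0.00786	0	0	none	NA
V21	F_193	PMS2	c.2149G>A	p.(Val717Met)	missense	41709	0.000758	0.595	0	none	NA
V22	F_170	MLH1	c.-117G>T	p.?	utr5	344901	0	NA	0.07	none	NA
V23	F_111	MSH6	c.1153_1155del	p.(Arg385del)	inframe_deletion	89177	0	0.5	0	none	NA
V24	F_240	PMS2	c.2335G>A	p.(Gly779Arg)	missense	127778	0.00000799	0.96	0.03	none	NA
V25	F_352	PMS2	c.241G>A	p.(Glu81Lys)	missense	182817	0.0000159	0.045	0	none	NA
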