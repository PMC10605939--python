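row	carrier_id	tissue_id	variant_id	tissue	age	ihc	mlh1_methylation	tmb	msi_positive_count	second_hit_events	other_events	printed_final
1	ID_326	CRC_326	V05	CRC	41	MLH1+/PMS2	NEGATIVE	110.7	5	MLH1:loh		dmmr_vus_plus_second_hit|MLH1
2	ID_149	CRC_149	V08	CRC	28	MSH2/MSH6	NT	108.2	6	MSH2:mut		dmmr_vus_plus_second_hit|MSH2
3	ID_315	EC_315	V10	EC	62	MSH2/MSH6	NT	77.3	6	MSH2:mut	MSH6:mut;PMS2:mut	dmmr_vus_plus_second_hit|MSH2
4	ID_315-2	EC_315-2	V10	EC	57	MLH1/PMS2+	POSITIVE	55.4	0			dmmr_mlh1_methylation|MLH1
5	ID_008	EC_008	V11	EC	62	MSH2/MSH6	NT	140.6	6	MSH2:loh	MLH1:mut;PMS2:mut	dmmr_vus_plus_second_hit|MSH2
6	ID_132	CRC_132	V12	CRC	37	MSH2/MSH6	NT	115.2	6	MSH2:mut		dmmr_vus_plus_second_hit|MSH2
7	ID_156	CRC_156	V13	CRC	61	MSH6	NT	79.8	5	MSH6:mut		dmmr_vus_plus_second_hit|MSH6
8	ID_156	EC_156	V13	EC	53	MSH6	NT	195	3			dmmr_vus_only|MSH6
9	ID_143	EC_143	V14	EC	29	PMS2	NEGATIVE	649.9	6	PMS2:mut;PMS2:mut	MSH2:mut;MSH2:mut;MSH6:mut;MSH6:mut;MLH1:mut	dmmr_vus_plus_second_hit|PMS2
10	ID_161	EC_161	V02	EC	59	MLH1/PMS2	NEGATIVE	99.8	6	MLH1:mut		dmmr_vus_plus_second_hit|MLH1
11	ID_051	EC_051	V01	EC	59	MLH1/PMS2	NEGATIVE	418	6	MLH1:loh;MLH1:mut	MSH6:mut	dmmr_vus_plus_second_hit|MLH1
12	ID_176	CRC_176	V04	CRC	47	MLH1/PMS2	NEGATIVE	102.7	6	MLH1:loh	MSH6:mut	dmmr_vus_plus_second_hit|MLH1
13	ID_176	EC_176	V04	EC	54	MLH1+/PMS2	NEGATIVE	52.4	5	MLH1:mut;MLH1:mut	MSH6:mut	dmmr_vus_plus_second_hit|MLH1
14	ID_058	EC_058	V07	EC	49	MSH2/MSH6	NT	102.2	6	MSH2:loh		dmmr_vus_plus_second_hit|MSH2
15	ID_138	CRC1_138	V09	CRC	66	MSH2/MSH6	NT	189	6	MSH2:mut;MSH2:mut	MSH6:mut;MSH6:mut	dmmr_vus_plus_second_hit|MSH2
16	ID_170	CRC_170	V22	CRC	35	Normal	NEGATIVE	10	3	MLH1:loh		dmmr_vus_plus_second_hit|MLH1
17	ID_111	CRC_111	V23	CRC	36	Normal	NT	40.4	5	MSH6:loh		dmmr_vus_plus_second_hit|MSH6
18	ID_376	CRC_376	V06	CRC	29	MSH2/MSH6	NT	156.6	6		MSH6:mut;PMS2:mut	dmmr_vus_only|MSH2
19	ID_328	CRC_328	V15	CRC	41	MSH2/MSH6	NT	39.9	6		MSH2:loh;MSH2:mut	dmmr_double_somatic|MSH2
20	ID_395	CRC_395	V17	CRC	38	MLH1/PMS2	NEGATIVE	111.2	6		MLH1:loh;MLH1:mut	dmmr_double_somatic|MLH1
21	ID_089	CRC1_089	V18	CRC	42	MLH1/PMS2	NEGATIVE	143.6	6		MLH1:loh;MLH1:mut;MLH1:mut	dmmr_double_somatic|MLH1
22	ID_046	EC_046	V19	EC	70	PMS2	NEGATIVE	371.1	4	MSH6:mut	PMS2:mut;PMS2:mut	dmmr_double_somatic|PMS2
23	ID_352	CRC2_352	V25	CRC	58	MSH2/MSH6	NT	162.6	5		MSH2:mut;MSH2:mut;MLH1:mut;MLH1:mut;MSH6:mut	dmmr_double_somatic|MSH2
24	ID_193	CRC_193	V21	CRC	32	MLH1/PMS2	NEGATIVE	79.3	5		MLH1:mut;MLH1:mut	dmmr_double_somatic|MLH1
25	ID_263	EC_263	V20	EC	62	MLH1+/PMS2	NEGATIVE	50.4	5	MSH6:mut	MLH1:loh;MLH1:mut	dmmr_double_somatic|MLH1
26	ID_202	EC_202	V16	EC	65	MSH6	NT	482.8	3	MSH2:mut	MSH6:mut;MSH6:mut	dmmr_double_somatic|MSH6
27	ID_240	CRC_240	V24	CRC	29	Normal	NEGATIVE	17.5	0			pmmr
28	ID_352	CRC1_352	V25	CRC	58	Normal	NT	208	1		MLH1:mut;MLH1:mut;MSH6:mut;MSH6:mut	pmmr
29	ID_161	EC_161	V03	EC	59	MLH1/PMS2	NEGATIVE	99.8	6		MLH1:mut	vus_benign_bystander
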