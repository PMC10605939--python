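tissue_id	carrier_id	tissue_label	lesion_class	age	ihc	mlh1_methylation	sequenced
EC_051	ID_051	EC	EC	59	MLH1/PMS2	NEGATIVE	true
Breast_051	ID_051	Breast	other_tumor	46	NT	NT	false
Duo_051	ID_051	Duodenal	other_tumor	58	NT	NT	false
Polyp1_051	ID_051	Tubulovillous adenoma	polyp	55	Normal	NT	false
Polyp2_051	ID_051	Tubulovillous adenoma	polyp	56	Normal	NT	false
Polyp3_051	ID_051	Tubulovillous adenoma	polyp	59	MLH1+/PMS2	NT	false
EC_161	ID_161	EC	EC	59	MLH1/PMS2	NEGATIVE	true
CRC_161	ID_161	CRC	CRC	34	Normal	NT	false
CRC_161-2	ID_161-2	CRC	CRC	35	Normal	NT	false
CRC1_161-3	ID_161-3	CRC	CRC	36	NT	NT	false
CRC2_161-3	ID_161-3	CRC	CRC	61	MLH1/PMS2	NT	false
Lung_161-3	ID_161-3	Lung	other_tumor	63	NT	NT	false
CRC_176	ID_176	CRC	CRC	47	MLH1/PMS2	NEGATIVE	true
EC_176	ID_176	EC	EC	54	MLH1+/PMS2	NEGATIVE	true
CRC_176-2	ID_176-2	CRC	CRC	82	PMS2	NT	false
CRC_326	ID_326	CRC	CRC	41	MLH1+/PMS2	NEGATIVE	true
CRC_376	ID_376	CRC	CRC	29	MSH2/MSH6	NT	true
EC_058	ID_058	EC	EC	49	MSH2/MSH6	NT	true
Skin_058	ID_058	Skin	other_tumor	47	NT	NT	false
Polyp_058-2	ID_058-2	Sessile serrated adenoma	polyp	19	NT	NT	false
CRC1_058-4	ID_058-3	CRC	CRC	52	NT	NT	false
CRC2_058-4	ID_058-3	CRC	CRC	54	NT	NT	false
CRC_058-5	ID_058-4	CRC	CRC	71	NT	NT	false
Prostate_058-5	ID_058-4	Prostate	other_tumor	74	NT	NT	false
CRC_149	ID_149	CRC	CRC	28	MSH2/MSH6	NT	true
CRC_149-2	ID_149-2	CRC	CRC	50	NT	NT	false
CRC1_138	ID_138	CRC	CRC	66	MSH2/MSH6	NT	true
CRC2_138	ID_138	CRC	CRC	78	NT	NT	false
Skin_138-2	ID_138-2	Skin (melanoma)	other_tumor	43	NT	NT	false
CRC_138-2	ID_138-2	CRC	CRC	64	Normal	NT	false
Pan_138-2	ID_138-2	Pancreatic	other_tumor	76	NT	NT	false
EC_315	ID_315	EC	EC	62	MSH2/MSH6	NT	true
CRC_315	ID_315	CRC	CRC	36	NT	NT	false
EC_315-2	ID_315-2	EC	EC	57	MLH1/PMS2+	POSITIVE	true
Polyp_315-2	ID_315-2	Benign endometrial polyp	polyp	59	NT	NT	false
EC_008	ID_008	EC	EC	62	MSH2/MSH6	NT	true
Ureter_008	ID_008	Ureter	other_tumor	45	NT	NT	false
CRC_008	ID_008	CRC	CRC	51	NT	NT	false
CRC_132	ID_132	CRC	CRC	37	MSH2/MSH6	NT	true
CRC_156	ID_156	CRC	CRC	61	MSH6	NT	true
EC_156	ID_156	EC	EC	53	MSH6	NT	true
EC_143	ID_143	EC	EC	29	PMS2	NEGATIVE	true
CRC_328	ID_328	CRC	CRC	41	MSH2/MSH6	NT	true
Breast_328	ID_328	Breast	other_tumor	54	NT	NT	false
EC_202	ID_202	EC	EC	65	MSH6	NT	true
Breast_202	ID_202	Breast	other_tumor	62	NT	NT	false
CRC_395	ID_395	CRC	CRC	38	MLH1/PMS2	NEGATIVE	true
CRC1_089	ID_089	CRC	CRC	42	MLH1/PMS2	NEGATIVE	true
CRC2_089	ID_089	CRC	CRC	44	NT	NT	false
EC_046	ID_046	EC	EC	70	PMS2	NEGATIVE	true
EC_263	ID_263	EC	EC	62	MLH1+/PMS2	NEGATIVE	true
CRC_193	ID_193	CRC	CRC	32	MLH1/PMS2	NEGATIVE	true
CRC_170	ID_170	CRC	CRC	35	Normal	NEGATIVE	true
CRC_111	ID_111	CRC	CRC	36	Normal	NT	true
CRC_240	ID_240	CRC	CRC	29	Normal	NEGATIVE	true
CRC1_352	ID_352	CRC	CRC	58	Normal	NT	true
CRC2_352	ID_352	CRC	CRC	58	MSH2/MSH6	NT	true
Brain_352	ID_352	Glioblastoma	other_tumor	52	NT	NT	false
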