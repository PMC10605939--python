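carrier_id	family_id	relationship	sex	carried_variants	is_proband	obligate
ID_051	F_051	Index	F	V01	true	false
ID_161	F_161	Index	F	V02,V03	true	false
ID_161-2	F_161	Son	M	V02	false	false
ID_161-3	F_161	Sister	F	V02	false	false
ID_176	F_176	Index	F	V04	true	false
ID_176-2	F_176	Mother	F	V04	false	false
ID_326	F_326	Index	F	V05	true	false
ID_376	F_376	Index	M	V06	true	false
ID_058	F_058	Index	F	V07	true	false
ID_058-2	F_058	Daughter	F	V07	false	false
ID_058-3	F_058	Mother	F	V07	false	false
ID_058-4	F_058	Maternal uncle	M	V07	false	true
ID_058-5	F_058	Maternal cousin	F	V07	false	false
ID_149	F_149	Index	M	V08	true	false
ID_149-2	F_149	Mother	F	V08	false	false
ID_138	F_138	Index	M	V09	true	false
ID_138-2	F_138	Brother	M	V09	false	false
ID_315	F_315	Index	F	V10	true	false
ID_315-2	F_315	Sister	F	V10	false	false
ID_008	F_008	Index	F	V11	true	false
ID_132	F_132	Index	F	V12	true	false
ID_156	F_156	Index	F	V13	true	false
ID_156-2	F_156	Brother	M	V13	false	false
ID_143	F_143	Index	F	V14	true	false
ID_143-2	F_143	Brother	M	V14	false	false
ID_143-3	F_143	Father	M	V14	false	false
ID_143-4	F_143	Paternal aunt	F	V14	false	false
ID_143-5	F_143	Paternal aunt	F	V14	false	false
ID_143-6	F_143	Paternal aunt	F	V14	false	false
ID_143-7	F_143	Paternal grandmother	F	V14	false	true
ID_143-8	F_143	Paternal aunt	F	V14	false	false
ID_328	F_328	Index	F	V15	true	false
ID_202	F_202	Index	F	V16	true	false
ID_395	F_395	Index	F	V17	true	false
ID_089	F_089	Index	F	V18	true	false
ID_046	F_046	Index	F	V19	true	false
ID_263	F_263	Index	F	V20	true	false
ID_193	F_193	Index	M	V21	true	false
ID_170	F_170	Index	F	V22	true	false
ID_111	F_111	Index	F	V23	true	false
ID_240	F_240	Index	F	V24	true	false
ID_352	F_352	Index	M	V25	true	false
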