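row	group	carrier_id	screen_tissue	variant_id	gene	acmg_class	outcome	deficient_protein	amount_screened
1	reference	Ref_029	colonic_mucosa	NA	MLH1	5	found	MLH1	2 x 80 uM
2	reference	Ref_029-2	colonic_mucosa	NA	MLH1	5	found	MLH1	10 x 4 uM
3	reference	Ref_605	colonic_mucosa	NA	MLH1	5	found	MLH1	1 x 80 uM
4	reference	Ref_411	colonic_mucosa	NA	MSH2	5	not_found	NA	2 x 80 uM
5	reference	Ref_897	colonic_mucosa	NA	NA	NA	not_found	NA	3 x 80 uM
6	reference	Ref_972	colonic_mucosa	NA	NA	NA	not_found	NA	3 x 80 uM
7	test	ID_051	endometrium	V01	MLH1	3	not_found	NA	10 x 4 uM
8	test	ID_161	endometrium	V02	MLH1	3	not_found	NA	3 x 80 uM
9	test	ID_176	colonic_mucosa	V04	MLH1	3	not_found	NA	3 x 80 uM
10	test	ID_326	colonic_mucosa	V05	MLH1	4	not_found	NA	2 x 80 uM
11	test	ID_058	endometrium	V07	MSH2	3	found	MSH2	1 x 80 uM
12	test	ID_376	colonic_mucosa	V06	MSH2	3	not_found	NA	3 x 80 uM
13	test	ID_138	colonic_mucosa	V09	MSH2	3	not_found	NA	1 x 4 uM
14	test	ID_315-2	endometrium	V10	MSH2	4	found	MSH2	1 x 80 uM
15	test	ID_132	colonic_mucosa	V12	MSH2	4	not_found	NA	10 x 4 uM
16	test	ID_156	colonic_mucosa	V13	MSH6	4	found	MSH6	10 x 4 uM
17	test	ID_046	endometrium	V19	MSH6	3	not_found	NA	3 x 80 uM
18	test	ID_143	endometrium	V14	PMS2	4	failed	NA	3 x 80 uM
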