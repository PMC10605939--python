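variant_id	tumor_lr	seg_lr	n_families	n_tumors_concordant	n_tumors_discordant	case_ihc	printed_class
V01	0.41	NA	1	1	0	MLH1/PMS2	3
V02	0.41	NA	1	1	0	MLH1/PMS2	3
V03	4.06	NA	1	1	0	MLH1/PMS2	2
V04	6.52	NA	1	2	0	MLH1/PMS2	3
V05	153.04	1.96	5	3	0	MLH1+/PMS2	4
V06	42.51	NA	2	2	0	MSH2/MSH6	3
V07	42.51	NA	2	2	0	MSH2/MSH6	3
V08	6.52	NA	1	1	0	MSH2/MSH6	4
V09	4.06	NA	1	1	0	MSH2/MSH6	3
V10	1103.14	1.32	5	5	0	MSH2/MSH6	4
V11	16.48	1.44	2	2	0	MSH2/MSH6	4
V12	6.52	NA	2	1	0	MSH2/MSH6	4
V13	66.92	NA	3	3	0	MSH6	4
V14	0.65	3.083	2	2	0	PMS2	4
V15	0.01	9.45	2	0	1	MSH2/MSH6	3
V16	0.00014	0.14	4	1	3	MSH6	2
V17	0.11	NA	1	0	1	MLH1/PMS2	3
V18	0.11	NA	1	0	1	MLH1/PMS2	3
V19	0.11	NA	1	0	1	PMS2	3
V20	0	NA	4	0	4	MLH1+/PMS2	1
V21	26.47	0.308	2	2	0	MLH1/PMS2	3
V22	0.11	NA	1	0	1	Normal	3
V23	0.46	15.22	4	1	1	Normal	3
V24	0.11	NA	1	1	0	Normal	3
V25	0.02	NA	2	0	2	Normal	3
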