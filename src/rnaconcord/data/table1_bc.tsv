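sample_id	cohort	site	age	sex	stage	her2_score	er_score	pr_score	coverage_mln	rin
BC-1	BC	primary	39	female	T2N3aM0, IIIC	3	0	0	9.42	2.1
BC-10	BC	primary	48	female	T2N0M0, II	3	0	0	6.70	1
BC-12	BC	primary	60	female	T2N0M0, IIA	3	0	0	5.12	1
BC-13	BC	primary	69	female	T2N3M0, III C	3	8	4	9.03	1
BC-14	BC	primary	49	female	T2N2M0, IIIA	3	0	0	6.11	2.4
BC-17	BC	primary	59	female	T4N2M0	3	7	2	3.96	2.5
BC-18	BC	lymph node metastasis	47	female	T3N1M0, IIIA	3	0	0	6.62	2.3
BC-19	BC	primary	48	female	T1N0M0, I	3	5	5	9.07	1.1
BC-20	BC	lymph node metastasis	51	female	T2N0M0, II	3	0	0	10.22	2.3
BC-21	BC	primary	49	female	T1N3M0, IIIC	3	0	0	9.34	2.3
BC-22	BC	primary	47	female	T2N0M0, II	3	6	5	10.52	2
BC-23	BC	primary	46	female	T2N2M0, IIIA	3	7	6	8.39	2.1
BC-24	BC	primary	57	female	T2N0M0, IIA	3	6	4	11.21	1
BC-27	BC	primary	44	female	T2N0M0	3	0	0	13.82	2.2
BC-28	BC	ovary metastasis	53	female	T2N0M0, IIA	0	7	4	4.65	3.7
BC-29	BC	primary	65	female	T4N3M1,IV	3	0	0	12.56	2.2
BC-3	BC	primary	55	female	T2N1M0, IIIa	3	0	0	6.84	1
BC-4	BC	primary	58	female	T2N1M0, IIB	3	0	0	7.17	1
BC-46	BC	liver metastasis	27	female	T2N2M0	0	8	8	15.07	3.3
BC-48	BC	relapse in the scar	36	female	T3N1M0	1	0	0	20.54	NA
BC-49	BC	primary	54	female	T1N2M0	0	2	8	10.54	2
BC-50	BC	primary	51	female	T2N0M0	0	0	0	8.49	2.6
BC-51	BC	primary	38	female	T2N1M0	0	0	0	8.68	3
BC-52	BC	primary	78	female	T1N2M0	1	4	8	11.92	1.7
BC-53	BC	primary	50	female	T2N0M0	1	0	8	8.06	1.9
BC-54	BC	primary	50	female	T2N0M0	0	0	0	7.30	1.8
BC-55	BC	primary	71	female	T2N3M0	1	8	8	9.32	3.3
BC-56	BC	primary	60	female	T1N1M1	0	0	8	12.66	2.4
BC-57	BC	primary	55	female	T3N2M0	1	0	0	13.77	2.8
BC-58	BC	lymph node metastasis	55	female	T1N0M0	0	7	7	14.24	2.1
BC-59	BC	scar metastasis	61	female	T1N1M0	0	3	1	16.88	1.2
BC-60	BC	primary	33	female	T2N1M0	2	0	0	10.03	1.8
BC-61	BC	liver metastasis	38	female	T2N2M0	0	8	8	5.42	3
BC-62	BC	brain metastasis	44	female	T2N0M0	0	0	0	10.99	3
BC-63	BC	primary	66	female	T4N2M0	0	0	0	10.11	3.7
BC-64	BC	primary	60	female	T3N3M0	1	0	0	12.71	3.8
BC-65	BC	primary	42	female	T2N0M0	0	0	0	9.92	2.6
BC-66	BC	primary	55	female	T3N1M0	3	3	3	8.96	3.1
BC-9	BC	primary	57	female	T1N1M0, IIB	3	8	5	6.88	1
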