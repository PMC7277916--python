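sample_id	cohort	histology	age	sex	stage	pdl1_positive_cells	coverage_mln	rin
LuC_16	LC	squamous cell carcinoma	75	male	T3N2M1, IV	1%-50%	11.54	2.4
LuC_18	LC	squamous cell carcinoma	63	male	T2N1M0	0	15.45	3
LuC_19	LC	squamous cell carcinoma	65	male	T2N0M0	>50%	12.57	3
LuC_30	LC	Unidentified	79	male	T2NXM0	>50%	11.01	4.9
LuC_31	LC	adenocarcinoma	66	male	T3N2M0	1%-50%	10.27	4.5
LuC_32	LC	adeno-squamous cell carcinoma	70	male	T2N1M0	>50%	12.14	2.7
LuC_33	LC	squamous cell carcinoma	57	male	T3N0M0	0	14.12	3.8
LuC_42	LC	adenocarcinoma	67	male	T1N1M0	1%-50%	11.9	1.4
LuC_23	LC	adenocarcinoma	60	male	T2N0M0	0	12.06	3.2
LuC_24	LC	adenocarcinoma	67	male	T2N0M0	0	10.77	3.8
LuC_26	LC	small cell carcinoma	65	male	T3N2M0, IIIa	1%-50%	5.71	1.1
LuC_28	LC	adenocarcinoma	76	male	T2N0M0	0	12.37	1.8
LuC_29	LC	squamous cell carcinoma	65	male	T2N0M0	0	16.58	2.4
LuC_34	LC	adenocarcinoma	62	female	pT1bN0M0	0	11.82	2.3
LuC_35	LC	squamous cell carcinoma	75	male	T3N0M0	>50%	12.28	3.2
LuC_36	LC	adenocarcinoma	57	male	pT2N0M0	1%-50%	11.3	2.6
LuC_37	LC	squamous cell carcinoma	68	male	T3N1M0	0	11.93	2.3
LuC_38	LC	adenocarcinoma	68	male	pT2aN2M0	1%-50%	15.38	3.5
LuC_39	LC	adenocarcinoma	68	female	pT2pNXpM1	0	8.58
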