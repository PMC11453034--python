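# Accuracy of CD spectrum predictions for the IDP8 reference ensembles:
# RMSD (kMRE) between the measured CD spectrum and the spectrum predicted
# from each ensemble model, per prediction method / basis set.
# refinement_basis: basis set used to compute per-conformer CD during the
# maximum-entropy refinement of Group B ensembles ("-" where CD was not
# part of the refinement).
group	ensemble	ds_dtsc3	dssp_1sc3	hbss_3sc1	ds5_4sc1	pdbmd2cd	dichrocalc	refinement_basis
A	asyn-A	1.92	1.91	1.55	1.92	6.31	8.48	-
A	mevn-A	1.95	1.87	1.91	2.88	3.63	5.50	-
A	sic1-A	2.67	2.39	0.57	2.69	3.60	3.09	-
A	tk18-A	1.36	1.40	1.55	3.18	2.74	11.59	-
B	mevn-B	1.22	1.17	1.60	1.61	4.74	8.76	ds_dtsc3
B	actr-B	2.79	2.60	2.66	0.45	6.26	8.33	ds5_4sc1
B	cbpn-B	1.07	1.60	1.06	1.47	2.87	5.42	ds5_4sc1
B	p53t-B	1.33	1.43	1.66	1.89	6.41	15.61	ds_dtsc3
B	rsp8-B	2.74	2.07	4.29	0.96	6.91	10.49	ds5_4sc1
C	mevn-C	1.41	1.20	1.66	2.73	4.61	9.86	-
C	actr-C	4.89	3.95	3.97	3.59	7.02	6.97	-
C	cbpn-C	1.09	1.85	1.06	1.21	3.23	5.08	-
C	p53t-C	2.66	1.35	2.25	0.64	6.98	13.41	-
C	rsp8-C	3.07	1.83	4.34	2.48	7.08	9.33	-
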