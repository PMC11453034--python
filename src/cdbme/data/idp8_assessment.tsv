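# IDP8 ensemble model assessment: deviation of ensemble-predicted observables
# from the measured data, per model ensemble.
# saxs_chi: sqrt of the reduced chi2 vs the measured SAXS curve (scale-free).
# cs_ca/cs_cb/cs_co: RMSD of backbone CA/CB/CO chemical shifts, ppm.
# cd_rmsd: RMSD of CD intensities (DS-dTSC3 basis predictions), kMRE.
# Group A: previously deposited ensembles (NMR/SAXS-derived, no CD).
# Groups B/C: maximum-entropy-refined ensembles with (B) / without (C) CD data.
# Group 0: the unrefined simulation ensembles B and C were refined from.
# NA: observable not available for that ensemble.
group	ensemble	saxs_chi	cs_ca	cs_cb	cs_co	cd_rmsd
A	asyn-A	1.34	0.36	0.66	0.66	1.9
A	mevn-A	0.61	0.28	0.37	0.40	2.0
A	sic1-A	0.66	1.30	0.49	NA	3.1
A	tk18-A	0.96	0.56	1.01	0.52	1.4
B	mevn-B	0.39	0.34	0.38	0.52	1.2
B	actr-B	1.94	0.35	0.35	0.46	0.5
B	cbpn-B	1.65	0.69	0.38	0.62	1.6
B	p53t-B	0.92	0.36	0.34	0.53	1.3
B	rsp8-B	1.03	0.41	NA	0.60	1.0
C	mevn-C	0.37	0.34	0.32	0.37	1.4
C	actr-C	1.83	0.28	0.32	0.39	3.6
C	cbpn-C	1.64	0.67	0.40	0.62	2.0
C	p53t-C	0.91	0.28	0.32	0.47	2.7
C	rsp8-C	1.07	0.57	NA	0.64	2.5
0	mevn-0	0.71	0.53	0.35	0.64	2.0
0	actr-0	1.72	0.50	0.36	0.53	3.4
0	cbpn-0	2.94	0.93	0.49	0.70	2.5
0	p53t-0	0.92	0.39	0.29	0.72	2.1
0	rsp8-0	1.67	0.83	NA	0.59	2.9
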