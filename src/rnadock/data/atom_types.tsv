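type	lj_radius	lj_welldepth	lk_dgfree	lk_lambda	lk_volume	charge	donor	acceptor
CAbb	2.00	0.062	0.52	3.5	14.7	0.07	0	0
CObb	2.00	0.062	1.00	3.5	13.5	0.51	0	0
CAli	2.00	0.051	1.52	3.5	23.7	0.00	0	0
CAro	2.00	0.062	0.08	3.5	18.4	0.00	0	0
Nbb	1.75	0.161	-5.00	3.5	15.5	-0.47	1	0
Npol	1.75	0.161	-6.00	3.5	15.5	-0.60	1	0
Naro	1.75	0.161	-4.00	3.5	15.5	-0.35	0	1
Ncat	1.75	0.200	-10.00	6.0	16.5	0.50	1	0
OCbb	1.55	0.210	-5.00	3.5	10.8	-0.51	0	1
OH	1.55	0.210	-6.70	3.5	10.8	-0.50	1	1
OOC	1.55	0.210	-10.00	6.0	10.8	-0.65	0	1
Oest	1.55	0.150	-3.00	3.5	10.8	-0.30	0	1
S	1.90	0.450	-2.00	3.5	17.7	0.00	0	0
P	2.10	0.200	-4.00	3.5	25.0	1.20	0	0
Hpol	1.00	0.050	0.00	3.5	0.0	0.30	0	0
Hapol	1.20	0.050	0.00	3.5	0.0	0.00	0	0
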