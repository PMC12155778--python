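acronym	class_id	n_carbons	formula	confidence_level	detection_frequency_pct	max_conc_ng_L	legacy
PFPrA	PFCA	3	C3HF5O2	2b	63.27	6.45	true
PFBA	PFCA	4	C4HF7O2	1	95.92	44.83	true
PFPeA	PFCA	5	C5HF9O2	1	87.76	8.75	true
PFHxA	PFCA	6	C6HF11O2	1	100.00	48.92	true
PFHpA	PFCA	7	C7HF13O2	1	91.84	8.42	true
PFOA	PFCA	8	C8HF15O2	1	97.96	37.22	true
PFNA	PFCA	9	C9HF17O2	1	89.80	7.59	true
PFDeA	PFCA	10	C10HF19O2	1	79.59	4.40	true
PFUdA	PFCA	11	C11HF21O2	1	57.14	2.25	true
PFDoA	PFCA	12	C12HF23O2	1	51.02	0.09	true
PFPrS	PFSA	3	C3HF7O3S	2b	69.39	5.32	true
PFBS	PFSA	4	C4HF9O3S	1	100.00	26.77	true
PFPeS	PFSA	5	C5HF11O3S	1	79.59	0.16	true
PFHxS	PFSA	6	C6HF13O3S	1	91.84	3.73	true
PFHpS	PFSA	7	C7HF15O3S	1	59.18	0.14	true
PFOS	PFSA	8	C8HF17O3S	1	67.35	6.10	true
PFGdiA	PFdiOA	5	C5H2F6O4	1	46.94	1.51	false
HPFLCA_i n=4	H-PFCA	4	C4H2F6O2	3a	87.76	0.03	false
HPFLCA_i n=5	H-PFCA	5	C5H2F8O2	3a	77.55	0.01	false
HPFLCA_i n=6	H-PFCA	6	C6H2F10O2	3a	18.37	0.00	false
HPFLSA_i n=4	H-PFSA	4	C4H2F8O3S	2a	87.76	7.42	false
PFMOAA	PFECA	3	C3HF5O3	2a	10.20	0.43	false
PFMPA	PFECA	4	C4HF7O3	2a	4.08	0.81	false
HFPO-DA	PFECA	6	C6HF11O3	1	79.59	3.20	false
4:2 FTSA	FTSA	6	C6H5F9O3S	1	20.41	0.75	false
6:2 FTSA	FTSA	8	C8H5F13O3S	1	83.67	8.17	false
6:2 Cl-PFESA	Cl-PFESA	8	C8HClF16O4S	1	10.20	0.18	false
HPFESA_i n=4	H-PFESA	4	C4H2F8O4S	2a	12.24	0.24	false
FBSAA	PFSM	6	C6H4F9NO4S	2b	24.49	5.11	false
HNTf2	HNTf2	2	C2HF6NO4S2	2b	87.76	15.02	false
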