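gene_a	gene_b	anchors	evalue	mean_ks	sd_ks	duplicated_type
Pbr002398	Pbr029646	33	8.58E-49	0.19	0.09	segmental
Pbr000122	Pbr031922	33	3.71E-49	0.18	0.08	segmental
Pbr031548	Pbr010799	33	9.59E-56	0.03	0.03	segmental
Pbr000523	Pbr016102	32	1.77E-48	0.19	0.05	segmental
Pbr025002	Pbr019883	32	2.91E-46	0.25	0.23	segmental
Pbr018673	Pbr010843	31	9.14E-46	0.26	0.35	segmental
Pbr037452	Pbr017706	29	6.97E-47	0.03	0.09	segmental
Pbr007354	Pbr034242	29	5.27E-48	0.21	0.1	segmental
Pbr025301	Pbr009057	28	5.33E-38	0.18	0.06	segmental
Pbr018673	Pbr021534	27	5.31E-41	0.05	0.05	segmental
Pbr001424	Pbr002913	26	1.11E-41	0.22	0.09	segmental
Pbr002685	Pbr009294	26	1.67E-45	0.01	0.01	segmental
Pbr015297	Pbr025184	24	8.01E-30	0.27	0.34	segmental
Pbr010843	Pbr021534	22	4.27E-33	0.19	0.05	segmental
Pbr010799	Pbr018725	19	9.26E-29	0.28	0.35	segmental
Pbr039547	Pbr021316	18	1.25E-33	0.03	0.12	segmental
Pbr008639	Pbr001724	15	6.05E-20	0.23	0.25	segmental
Pbr013092	Pbr034115	14	6.10E-16	0.55	0.92	segmental
Pbr008278	Pbr029330	14	2.54E-18	0.23	0.15	segmental
Pbr031548	Pbr018725	13	1.72E-22	0.2	0.07	segmental
Pbr015073	Pbr004345	12	4.56E-20	0.25	0.28	segmental
Pbr011472	Pbr039129	12	9.50E-12	1.38	0.42	segmental
Pbr041812	Pbr018132	12	5.92E-19	0.09	0.28	segmental
Pbr019675	Pbr025184	11	2.87E-10	1.27	0.48	segmental
Pbr036688	Pbr002230	11	3.00E-20	0.05	0.13	segmental
Pbr019675	Pbr015297	10	6.23E-10	1.36	0.75	segmental
Pbr000122	Pbr041812	10	4.80E-14	1.25	0.62	segmental
Pbr039741	Pbr031922	10	2.94E-15	1.49	0.95	segmental
Pbr022698	Pbr041200	10	1.01E-18	0.19	0.06	segmental
Pbr000122	Pbr039741	9	2.71E-14	1.57	0.9	segmental
Pbr031922	Pbr018132	9	2.06E-10	1.34	0.43	segmental
Pbr019026	Pbr020001	9	9.84E-16	0.35	0.52	segmental
Pbr023691	Pbr039741	8	4.43E-14	0.1	0.27	segmental
Pbr000122	Pbr018132	8	1.57E-09	1.57	0.43	segmental
Pbr025301	Pbr004345	8	1.33E-08	1.04	0.63	segmental
Pbr041812	Pbr031922	8	1.14E-11	1.36	0.35	segmental
Pbr034242	Pbr020001	8	3.02E-06	1.49	0.42	segmental
Pbr002398	Pbr039547	7	2.62E-06	1.57	0.46	segmental
Pbr001238	Pbr014651	7	2.56E-11	0.18	0.05	segmental
Pbr039741	Pbr041812	7	1.94E-10	1.27	0.25	segmental
Pbr039741	Pbr018132	7	1.79E-08	1.38	0.25	segmental
Pbr041858	Pbr039129	7	7.25E-09	1.33	0.78	segmental
Pbr005390	Pbr000523	6	5.22E-08	1.59	0.56	segmental
Pbr004345	Pbr009057	6	2.11E-07	1.11	0.47	segmental
Pbr002685	Pbr018132	6	5.22E-08	0.2	0.08	segmental
Pbr018673	Pbr007956	6	1.91E-06	1.15	0.15	segmental
Pbr003660	Pbr014160	6	2.09E-12	0.02	0.03	segmental
Pbr007354	Pbr020001	6	2.82E-05	1.57	0.44	segmental
Pbr034115	Pbr014651	6	5.51E-06	1.43	0.5	segmental
Pbr002398	Pbr021316	5	1.44E-05	1.66	0.5	segmental
Pbr015073	Pbr025301	5	3.91E-07	1.01	0.21	segmental
Pbr015073	Pbr009057	5	3.02E-05	1.18	0.38	segmental
Pbr002913	Pbr014651	5	5.94E-06	1.27	0.45	segmental
Pbr036688	Pbr010843	5	1.38E-04	1.51	0.26	segmental
Pbr005390	Pbr016102	5	1.64E-06	1.9	0.56	segmental
Pbr002685	Pbr034115	5	1.44E-03	1.36	0.71	segmental
Pbr008639	Pbr007956	5	4.32E-04	1.72	0.86	segmental
Pbr001724	Pbr015019	5	2.97E-05	1.51	0.42	segmental
Pbr007956	Pbr010843	5	1.13E-03	1.11	0.33	segmental
Pbr025184	Pbr019026	5	5.60E-03	1.59	0.49	segmental
Pbr025184	Pbr018725	5	3.98E-06	1.51	0.79	segmental
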