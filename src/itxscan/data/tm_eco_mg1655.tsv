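no	sequence	length	type	start	end	minutes	strand
1	CCCTCTCCCTGTGGGAGAGGGCCGGGGTGAGGGC	34	B	164547	164580	3.5	+
2	CCCTCTCCCTTGAGGGAGAGGGTTAGGGTGAGGGT	35	A	164631	164597	3.5	-
3	CCCTCGCCCCTTTGGGGAGAGGGCCGGGGTGAGGGG	36	B mm	282101	282136	6	+
4	CCCTCTCCCTGTGGGAGAGGGCCGGGGTGAGGGC	34	B	289246	289279	6.2	+
5	CCCTCGCCCCCTTGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	388664	388699	8	+
6	CCCTCGCCCCCTCGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	497843	497878	11	+
7	CCCTCGCCCCTTTGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	624579	624614	13	+
8	CCCTCTCCCTTCCAGGGTGAGGGCTGGGGTGAGGGT	36	B	624676	624641	13	-
9	CCCTCGCCCCTCTGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	1351239	1351204	29	-
10	CCCTCGCCCTTTCAGGGAGAGGGCCGGGGTGAGGGT	36	B mm	3045989	3046024	66	+
11	CCCTCGCCCCTTTGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	3046087	3046052	66	-
12	CCCTCTCCCTTCCAGGGAGAGGGTCGGGGTGAGGGT	36	B	3239599	3239634	70	+
13	CCCTCGCCCCGTTTGGGGAGAGGGTTAGGGTGAGGGG	37	A mm	3239698	3239662	70	-
14	CCCTCGCCCCTTTGGGGTGAGGGTTAGGGTGAGGGG	36	A mm	3390529	3390494	73	-
15	CCCTCGCCCCTTTGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	3504892	3504857	75.5	-
16	CCCTCGCCCCTCTGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	3608684	3608719	78	+
17	CCCTCTCCCTGAGGGAGAGGGTTAGGGTGAGGGG	34	A	3781061	3781028	81.5	-
18	CCCTCGCCCCTCCGGGGAGAGGGCCGGGGTGAGGGG	36	B mm	3781121	3781156	81.5	+
19	CCCTCGCCCCTCTGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	3908495	3908530	84	+
20	CCCTCTCCCTGTGGGAGAGGGTCGGGGTGAGGGC	34	B	3959491	3959458	85	-
21	CCCTCGCCCCTTTGGGGAGAGGGTTAGGGAGAGGGG	36	A mm	4070452	4070487	88	+
22	CCCTCGCCCCTCTGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	4314285	4314320	93	+
23	CCCTCGCCCCTCCGGGGAGAGGGTTAGGGTGAGGGG	36	A mm	4549883	4549848	98	-
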