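group	source	NC	CI	CP	EA	EP	SC	WA	WI	NP
corals	NC	8.58/7.6	1.51	1.13	0.26	0.22	0.24	0.42	0.96	0.19
corals	CI	0.49	1068.8/301.42	22.38	1.64	6.65	1.89	2.66	33.28	1.85
corals	CP	0.38	7.07	939.38/276.96	1.42	6.94	1.68	2.63	26.62	1.55
corals	EA	0.12	1.64	1.62	13.4/8.12	0.29	0.27	0.82	1.22	0.22
corals	EP	0.1	2.22	3.35	0.34	13.34/9.74	0.27	0.9	1.3	0.21
corals	SC	0.18	2.43	1.88	0.42	0.35	12.8/11	0.47	1.39	0.31
corals	WA	1.15	2.08	2.45	4.31	1.01	0.25	111.58/13.72	1.73	0.25
corals	WI	0.34	6.52	13.74	1.02	4.26	0.87	1.9	755.44/237.6	1.33
corals	NP	0.17	2.58	1.89	0.37	0.33	0.35	0.42	1.73	12.56/11.14
cetaceans	NC	16.72/2.48	0.77	0.72	1.38	0.62	1.09	1.92	0.02	2.3
cetaceans	CI	0.66	45.86/11.22	0.88	2.39	1.78	1.6	2.14	0.58	1.08
cetaceans	CP	1.2	5.52	62.46/13.32	3.65	3.71	4.67	4.52	0.6	2.39
cetaceans	EA	2.38	2.78	1.03	38.62/6.98	1.19	2	4.6	0.53	0.8
cetaceans	EP	0.96	4.05	2.6	4.39	50.46/10.88	3.39	4.52	0.58	3.08
cetaceans	SC	0.71	2.14	3.92	1.32	3.81	28.56/6.64	2.56	0.07	1.24
cetaceans	WA	2.46	2.55	1.41	3.93	1.78	2.36	43.42/8.78	0.57	0.71
cetaceans	WI	0.2	1.05	0.12	0.1	0.04	0.1	0.14	0.98/0.7	0.02
cetaceans	NP	1.59	1.28	0.83	0.32	1.16	1.09	0.65	0.05	7.22/2.36
seagrass	NC	0.3/0.94	0.5	0.14	1.38	0.08	0.12	0.81	0.71	0.13
seagrass	CI	1.37	49.66/8.7	8.56	1.88	0.94	6.65	2.65	5.93	3.74
seagrass	CP	0.14	1.54	1.34/2.7	0.25	0.22	0.82	0.96	1.14	0.21
seagrass	EA	0.91	0.5	0.2	0.48/1.32	0.12	0.26	0.25	0.55	0.11
seagrass	EP	0.08	0.51	0.42	0.24	0.94/1.84	0.2	0.49	0.28	0.61
seagrass	SC	0.19	1.58	1.24	0.36	0.84	1.86/2.4	0.45	0.46	0.2
seagrass	WA	0.2	1.6	1.75	1.21	1.37	0.25	14.98/6.32	1.64	0.2
seagrass	WI	0.35	2.28	2.08	1.94	0.43	0.4	0.95	5.94/3.08	0.15
seagrass	NP	1.13	2.66	0.25	1.09	1.73	0.48	0.49	0.51	11.74/2.54
fish	NC	5017.2/2861.78	457.6	381.47	399.38	325.61	365.6	455.76	386.69	332.59
fish	CI	585.82	13900.96/5283.3	807.38	543.94	521.04	560.8	680.89	861.31	466.3
fish	CP	435.95	609.31	8926.54/4145.48	456.42	466.48	437.45	559.07	597.81	338.5
fish	EA	392.11	450.19	362.52	4262/2423.34	345.82	297.5	449.42	379.71	255.35
fish	EP	337.4	464.22	393.19	382.18	4048.06/2309.96	288.4	436.48	329.46	315.72
fish	SC	374.92	463.23	392.53	362.82	304.76	3556.66/2369.68	400.39	343.8	262.44
fish	WA	473.7	474.58	439.01	503.81	429.67	366.53	5640.38/2879.26	408.37	291.23
fish	WI	370.32	533.07	435.47	426.45	346.1	328.19	449.97	7048.18/3454.1	276.3
fish	NP	272.2	382.34	292.64	267.99	269.19	226.41	272.91	255.5	3201.6/2006
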