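group	realm	emigration	immigration	extinction	in_situ_speciation
Seagrasses	NC	0.9675	1.0925	0.235	0.075
Seagrasses	CI	0.737209	0.260465	0.202326	1.154884
Seagrasses	CP	0.48	1.327273	0.245455	0.121818
Seagrasses	EA	0.414286	1.194286	0.188571	0.068571
Seagrasses	EP	0.564	1.148	0.368	0.188
Seagrasses	SC	0.591111	1.02	0.266667	0.206667
Seagrasses	WA	0.914444	0.782222	0.702222	1.664444
Seagrasses	WI	0.78	1.018182	0.28	0.54
Seagrasses	NP	0.695	0.445	0.211667	0.978333
Corals	NC	4.94	2.93	7.6	8.58
Corals	CI	0.14303	0.052525	0.608929	2.159192
Corals	CP	0.140816	0.141108	0.807464	2.738717
Corals	EA	0.688889	1.085556	0.902222	1.488889
Corals	EP	0.724167	1.675	0.811667	1.111667
Corals	SC	7.42	5.81	11	12.8
Corals	WA	0.244444	0.188889	0.254074	2.066296
Corals	WI	0.106007	0.240989	0.839576	2.669399
Corals	NP	7.83	5.92	11.14	12.56
Cetaceans	NC	0.801818	0.927273	0.225455	1.52
Cetaceans	CI	0.411111	0.744444	0.415556	1.698519
Cetaceans	CP	0.79697	0.348485	0.403636	1.892727
Cetaceans	EA	0.765	0.875	0.349	1.931
Cetaceans	EP	0.907692	0.542308	0.418462	1.940769
Cetaceans	SC	0.79	0.815	0.332	1.428
Cetaceans	WA	0.585185	0.777778	0.325185	1.808148
Cetaceans	WI	1.77	3	0.7	0.98
Cetaceans	NP	0.774444	1.288889	0.262222	0.802222
Fishes	NC	1.413156	1.475837	1.302585	2.28366
Fishes	CI	0.796118	0.60721	0.836627	2.20126
Fishes	CP	1.075245	0.965882	1.142635	2.460458
Fishes	EA	1.331196	1.517468	1.100018	1.934635
Fishes	EP	1.542146	1.574392	1.20877	2.118294
Fishes	SC	2.299987	2.273065	1.876231	2.816041
Fishes	WA	1.176005	1.286418	0.999743	1.958465
Fishes	WI	1.089797	1.226387	1.189019	2.426224
Fishes	NP	1.875361	2.125989	1.680067	2.681407
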