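species	identical	compared	identity_pct	ddr	domain
Mm	145	282	51.4	0.784	euryarchaeota
Mfe	144	282	51.1	0.820	euryarchaeota
Mt	141	282	50.0	0.828	euryarchaeota
Af	140	282	49.6	0.862	euryarchaeota
Mj	139	282	49.3	0.869	euryarchaeota
Mb	139	282	49.3	0.886	euryarchaeota
Min	135	282	47.9	0.918	euryarchaeota
Sa	133	282	47.2	0.957	crenarchaeota
Mma	133	282	47.2	0.963	euryarchaeota
Tv	128	282	45.4	0.988	euryarchaeota
Ta	130	282	46.1	0.991	euryarchaeota
Fa	131	282	46.5	0.993	euryarchaeota
Fpl	125	282	44.3	1.04	euryarchaeota
Mth	125	282	44.3	1.04	euryarchaeota
St	126	282	44.7	1.04	crenarchaeota
Ma	127	282	45.0	1.04	euryarchaeota
Ss	125	282	44.3	1.05	crenarchaeota
Pf	120	282	42.6	1.06	euryarchaeota
Pw	120	282	42.6	1.06	euryarchaeota
Abo	121	282	42.9	1.10	euryarchaeota
Pab	114	282	40.4	1.15	euryarchaeota
Ph	114	282	40.4	1.17	euryarchaeota
Ap	117	297	39.4	1.19	crenarchaeota
Hsp	118	282	41.8	1.24	euryarchaeota
Pae	113	282	40.1	1.26	crenarchaeota
Sp	115	282	40.8	1.28	eukaryote
Ce	113	282	40.1	1.33	eukaryote
Dm	108	282	38.3	1.44	eukaryote
Hs	110	282	39.0	1.48	eukaryote
Xl	105	282	37.2	1.56	eukaryote
Gg	103	282	36.5	1.59	eukaryote
Mmu	106	282	37.6	1.59	eukaryote
Sc	102	282	36.2	1.68	eukaryote
At	92	282	32.6	1.95	eukaryote
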