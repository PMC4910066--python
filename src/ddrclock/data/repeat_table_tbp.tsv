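species	identical	compared	identity_pct	ddr	domain
Mj	168	273	61.5	0.488	euryarchaeota
Mm	167	276	60.5	0.516	euryarchaeota
Mfe	164	273	60.1	0.524	euryarchaeota
Min	164	276	59.4	0.524	euryarchaeota
Mt	160	276	58.0	0.560	euryarchaeota
Mth	155	273	56.8	0.619	euryarchaeota
St	157	276	56.9	0.619	crenarchaeota
Ap	154	276	55.8	0.639	crenarchaeota
Hsp	156	279	55.9	0.656	euryarchaeota
Ss	152	276	55.1	0.672	crenarchaeota
Abo	143	279	51.3	0.699	euryarchaeota
Af	143	279	51.3	0.726	euryarchaeota
Fpl	138	279	49.5	0.737	euryarchaeota
Pae	144	276	52.2	0.740	crenarchaeota
Fa	141	279	50.5	0.755	euryarchaeota
Ta	141	279	50.5	0.759	euryarchaeota
Sa	141	276	51.1	0.774	crenarchaeota
Mb	135	279	48.4	0.814	euryarchaeota
Ph	135	276	48.9	0.816	euryarchaeota
Ma	132	279	47.3	0.855	euryarchaeota
Pab	131	276	47.5	0.879	euryarchaeota
Tv	130	279	46.6	0.902	euryarchaeota
Pf	127	276	46.0	0.930	euryarchaeota
Pw	127	276	46.0	0.930	euryarchaeota
Mma	127	279	45.5	0.933	euryarchaeota
Sp	125	273	45.8	1.00	eukaryote
Sc	121	273	44.3	1.01	eukaryote
Dm	118	276	42.8	1.05	eukaryote
Xl	119	276	43.1	1.06	eukaryote
At	119	279	42.7	1.07	eukaryote
Mmu	111	276	40.2	1.14	eukaryote
Hs	113	276	40.9	1.14	eukaryote
Gg	110	276	39.9	1.19	eukaryote
Ce	110	273	40.3	1.22	eukaryote
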