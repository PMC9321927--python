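species	suborder	clade	group	gene_size	i1	i2	i3	i4	i5	i6	i7
Trematomus_bernacchii	Notothenioidei	antarctic	focal	8310	628	2372	548	2825	124	146	111
Gymnodraco_acuticeps	Notothenioidei	antarctic	focal	8235	583	2866	552	2906	124	85	111
Pseudochaenichthys_georgianus	Notothenioidei	antarctic	focal	9013	582	3080	538	2939	133	85	111
Cottoperca_gobio	Notothenioidei	non_antarctic_notothenioid	comparison	5930	596	1519	204	1713	156	129	115
Sander_lucioperca	Percoidei	temperate	comparison	4818	649	124	211	1080	161	155	115
Perca_fluviatilis	Percoidei	temperate	comparison	3976	590	126	211	1237	171	137	122
Perca_flavescens	Percoidei	temperate	comparison	6669	554	125	211	1229	171	156	115
Etheostoma_spectabile	Percoidei	temperate	comparison	5939	579	124	153	1014	143	137	115
Etheostoma_cragini	Percoidei	temperate	comparison	3700	595	124	207	985	143	145	117
Epinephelus_lanceolatus	Serranoidei	temperate	comparison	5831	588	117	206	2969	163	93	107
Plectropomus_leopardus	Serranoidei	temperate	comparison	7090	545	1304	183	2135	161	150	118
Sebastes_umbrosus	Scorpaenoidei	temperate	comparison	6887	601	779	208	2631	634	133	118
Pungitius_pungitius	Cottoidei	temperate	comparison	5126	579	461	196	872	136	167	96
Anarrhichthys_ocellatus	Cottoidei	temperate	comparison	5432	595	593	205	1369	176	153	106
Gasterosteus_aculeatus	Cottoidei	temperate	comparison	4095	577	274	195	1210	89	159	99
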