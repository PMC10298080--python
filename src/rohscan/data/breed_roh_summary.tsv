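# Published breed-level ROH summary statistics for a 97-horse, 16-breed
# whole-genome resequencing panel: per-breed segment counts, total/mean/max
# lengths (Mb) and per-length-class counts. Used as arithmetic validation
# input for the summary statistics this package computes.
population	n_samples	total_n_roh	mean_n_roh	total_length_mb	total_mean_length_mb	max_length_mb	n_lt1mb	n_1_5mb	n_5_10mb	n_gt10mb
Friesian	5	3183	637	3178.47	635.69	7.82	2116	1060	7	0
Thoroughbred	22	12490	568	13526.86	614.86	13.89	8233	4130	117	10
Arabian	5	3104	621	3013.17	602.63	7.34	2119	970	15	0
Shetland pony	3	1435	478	1545.37	515.12	8.18	918	504	13	0
Andalusian	4	2102	526	2047.94	511.99	8.47	1428	667	7	0
Akhal-Teke	5	2112	422	1997.03	399.41	8.37	1508	599	5	0
Standardbred	4	1549	387	1550.21	387.55	11.38	1094	437	17	1
Hanoverian	4	1282	321	1207.67	301.92	7.32	918	360	4	0
American Quarter Horse	7	2173	310	1997.14	285.31	8.99	1587	575	11	0
Franches-Montagnes	6	1476	246	1649.65	274.94	10.56	939	520	16	1
Criollo	2	491	246	403.68	201.84	4.12	390	101	0	0
Jeju	2	501	251	369.51	184.76	4.13	417	84	0	0
Przewalskii	10	1802	180	1591.60	159.16	8.74	1378	423	1	0
Mongolian	5	993	199	785.24	157.05	4.70	809	184	0	0
Debao	5	836	167	593.08	118.62	5.06	712	123	1	0
Yakutian	7	711	102	459.81	65.69	2.91	639	72	0	0
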