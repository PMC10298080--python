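# Published mean genomic inbreeding coefficients (F_ROH = L_ROH / L_AUTO,
# L_AUTO = 2280.94 Mb) by ROH length class for the same 16-breed horse
# panel; SD of F_ROH-all reported only for breeds with more than 3 samples
# (NA otherwise). Used as arithmetic validation input.
population	n_samples	f_roh_lt1mb	f_roh_1_5mb	f_roh_5_10mb	f_roh_gt10mb	f_roh_all	sd_f_roh_all
Friesian	5	1.16e-1	1.59e-1	3.81e-3	0	2.79e-1	3.11e-4
Arabian	5	1.15e-1	1.41e-1	7.50e-3	0	2.64e-1	3.12e-4
Thoroughbred	23	9.73e-2	1.44e-1	1.42e-2	2.27e-3	2.58e-1	4.25e-4
Andalusian	4	9.69e-2	1.23e-1	4.87e-3	0	2.24e-1	3.13e-4
Shetland pony	3	8.26e-2	1.31e-1	1.19e-2	0	2.26e-1	3.93e-4
Akhal-Teke	5	8.14e-2	9.06e-2	3.06e-3	0	1.75e-1	3.17e-4
Standardbred	4	7.33e-2	8.39e-2	1.15e-2	1.25e-3	1.70e-1	3.93e-4
Hanoverian	4	6.00e-2	6.95e-2	2.79e-3	0	1.32e-1	3.25e-4
American Quarter Horse	7	5.94e-2	6.15e-2	4.22e-3	0	1.25e-1	3.26e-4
Jeju	2	5.41e-2	2.69e-2	0	0	8.10e-2	NA
Criollo	2	5.19e-2	3.66e-2	0	0	8.85e-2	NA
Franches-Montagnes	5	4.96e-2	8.53e-2	8.80e-3	9.26e-4	1.45e-1	4.43e-4
Mongolian	5	4.26e-2	2.63e-2	0	0	6.89e-2	2.21e-4
Debao	5	3.54e-2	1.62e-2	4.44e-4	0	5.20e-2	1.90e-4
Przewalskii	10	3.50e-2	3.44e-2	3.83e-4	0	6.98e-2	3.10e-4
Yakutian	7	2.26e-2	6.20e-3	0	0	2.88e-2	1.33e-4
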