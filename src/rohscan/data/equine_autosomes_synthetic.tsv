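# synthetic per-chromosome apportionment of the 2,280.94 Mb equine autosome total
# chromosome sizes are illustrative; only the exact total is meaningful
1	190500558
2	122609391
3	121596090
4	110449782
5	101330075
6	88157165
7	100316774
8	95250270
9	85117263
10	85117263
11	61811346
12	33438924
13	43571932
14	95250270
15	93223669
16	89170466
17	82077361
18	83090661
19	60798045
20	65864549
21	57758143
22	50665037
23	55731541
24	47625135
25	40532030
26	42558631
27	40532030
28	46611834
29	34452225
30	30399022
31	25332518
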