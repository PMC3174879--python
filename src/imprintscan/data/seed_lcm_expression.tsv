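# Mean seed-tissue expression (globular stage) of 18 maternally expressed
# candidate imprinted genes, from the Harada-Goldberg Arabidopsis thaliana
# Laser Capture Microdissection GeneChip dataset (seedgenenetwork.net;
# GEO GSM284384-GSM284398). Values are replicate means per tissue fraction.
# reference_abs_difference / reference_ratio / reference_rank are the
# enrichment statistics (hEF-SC, hEF/SC) reported for these genes; the
# derived columns were computed from inputs already rounded to 2 decimals,
# so recomputation can differ by +/-0.01.
gene_id	seed_coat	embryo	peripheral_endosperm	micropylar_endosperm	chalazal_endosperm	reference_abs_difference	reference_ratio	reference_rank
At3g09840	9462.69	12859.55	8565.74	7199.95	15983.67	6520.97	1.69	1
At5g16620	1882.19	3721.39	7328.89	1547.72	594.65	5446.69	3.89	2
At3g51280	143.71	6909.54	3598.61	425.12	170.39	3454.9	25.04	3
At4g16830	1403.41	2234.66	3777.26	3520.61	1358.85	2373.85	2.69	4
At5g63330	364.44	215.12	512.38	340.48	1942.53	1578.09	5.33	5
At1g73680	2286.18	68.31	1281.93	3787.4	1095.28	1501.21	1.66	6
At1g03070	150.95	22.77	43.96	70.68	1273.49	1122.55	8.44	7
At3g24530	839.73	1359.11	1940.84	1502.07	352.68	1101.11	2.31	8
At1g65820	757.13	253.23	413.46	1813.32	612.73	1056.2	2.39	9
At3g17000	416.34	137.53	165.76	440.71	1401.76	985.42	3.37	10
At5g39510	1934.73	812.5	1357.99	2472.39	2071.39	537.65	1.28	11
At1g25370	362.23	56.59	52.88	339.09	718.4	356.17	1.98	12
At3g59380	333.7	299	481.63	597.3	631.7	298.01	1.89	13
At3g55250	183.62	264.14	461.66	219.78	83.6	278.04	2.51	14
At2g31510	398.3	455.28	416.09	642.15	195.12	243.85	1.61	15
At2g16480	620.32	793.04	854.07	611.2	577.62	233.75	1.38	16
At1g61990	265.14	479.11	335.01	403.18	470.95	205.81	1.78	17
At2g32000	280.44	244.55	333.14	176.92	98.83	52.7	1.19	18
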