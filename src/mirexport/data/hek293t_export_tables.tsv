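mirna	list	nt_cell_rpmm	nt_ev_rpmm	nt_log2_printed	tf_cell_rpmm	tf_ev_rpmm	tf_log2_printed
mir-451	released	0.4	3945.0	13.3	1.7	7982.5	12.2
mir-150	released	0.4	2475.0	12.6	0.3	663.0	10.9
mir-146a	released	10.4	1321.2	7.0	317863.3	440496.3	0.5
mir-320c	released	24.3	2347.5	6.6	57.8	1803.4	5.0
mir-143	released	39.9	3232.5	6.3	8327.3	354.4	8.5
mir-720	released	65.4	3157.5	5.6	3208.9	46.2	5.5
mir-125a-5p	released	214.7	9360.0	5.4	439.0	2121.6	2.3
mir-486	released	105.7	3900.0	5.2	72.8	7637.8	6.7
mir-149	released	89.0	3142.5	5.1	85.3	928.2	3.4
mir-2110	released	43.5	1380.0	5.0	175.0	928.2	2.4
mir-320a	released	762.1	23190.0	4.9	1250.0	11483.2	3.2
mir-197	released	472.4	8347.5	4.1	724.0	6046.6	3.1
mir-339	released	91.4	1515.0	4.1	178.0	610.0	1.8
mir-99b	released	2065.2	27420.0	3.7	4900.0	8353.8	0.8
mir-4286	released	108.5	1245.0	3.5	72.1	1617.7	4.5
mir-92b	released	515.1	5542.5	3.4	484.0	4800.1	3.3
mir-222	released	774.1	7882.5	3.3	1200.0	10634.5	3.1
mir-423-5p	released	5737.2	55762.5	3.3	5290.0	22435.9	2.1
mir-877	released	467.2	4425.0	3.2	2000.0	2121.6	0.1
mir-191	released	9501.8	88717.5	3.2	15000.0	40893.8	1.4
mir-1292	released	140.0	1222.5	3.1	256.0	397.8	0.6
mir-1246	released	782.8	6570.0	3.1	156.0	11456.6	6.2
mir-218	retained	1342.24	135.00	-3.31	1460.00	132.60	-3.46
mir-15a	retained	2411.56	435.00	-2.47	2120.00	371.28	-2.51
mir-140	retained	1181.04	277.50	-2.09	1130.00	185.64	-2.61
mir-148b	retained	18756.99	5047.50	-1.89	17300.00	5383.56	-1.68
mir-378	retained	397404.00	109560.00	-1.86	192000.00	117695.76	-0.71
mir-16	retained	7225.49	2100.00	-1.78	7190.00	2625.48	-1.45
mir-20a	retained	45087.00	14460.00	-1.64	52700.00	14957.28	-1.82
mir-424	retained	1230.92	397.50	-1.63	878.00	477.36	-0.88
mir-18a	retained	4535.03	1477.50	-1.62	4520.00	1405.56	-1.69
let-7f	retained	16253.27	5520.00	-1.56	31964.69	11055.00	-1.53
let-7g	retained	4999.47	1950.00	-1.36	5580.00	4826.64	-0.21
mir-130b	retained	2194.90	877.50	-1.32	2180.00	769.08	-1.50
mir-15b	retained	2820.93	1147.50	-1.30	2780.00	1087.32	-1.35
mir-598	retained	1066.13	435.00	-1.29	1400.00	397.80	-1.82
mir-26b	retained	1594.80	660.00	-1.27	1440.00	689.52	-1.06
mir-340	retained	4503.91	2137.50	-1.08	1870.00	2280.72	0.29
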