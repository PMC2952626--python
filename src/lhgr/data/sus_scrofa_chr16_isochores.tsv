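no	start	stop	length	gc	family	h
1	1	561070	561070	40.93	L2	0.0091
2	561071	1129138	568068	39.12	L2	0.0262
3	1129139	2265069	1135931	36.00	L1	0.0408
4	2265070	2709575	444506	39.39	L2	0.0413
5	2709576	3036775	327200	43.25	H1	0.0529
6	3036776	3497556	460781	45.24	H1	0.0850
7	3497557	5126374	1628818	40.81	L2	0.1427
8	6354085	11524640	5170556	35.01	L1	0.1136
9	11524641	12254555	729915	33.41	L1	0.0631
10	43172563	44816542	1643980	39.60	L2	0.0487
11	44816543	45306029	489487	41.59	H1	0.0590
12	45306030	45953195	647166	43.80	H1	0.0576
13	45953196	46406468	453273	42.05	H1	0.0381
14	46406469	46773633	367165	40.13	L2	0.0359
15	46773634	48635681	1862048	45.71	H1	0.0476
16	48635682	49272472	636791	50.27	H2	0.0683
17	49272473	49934493	662021	45.02	H1	0.0694
18	49934494	50634448	699955	39.51	L2	0.0744
19	50634449	51009856	375408	50.03	H2	0.1071
20	51009857	51324060	314204	47.14	H2	0.1247
21	51324061	51885056	560996	42.73	H1	0.1853
22	70778047	71335207	557161	42.23	H1	0.1917
23	71335208	72505936	1170729	44.82	H1	0.0794
24	72505937	72972167	466231	51.57	H2	0.1952
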