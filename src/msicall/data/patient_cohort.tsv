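sample_id	subgroup	ihc_status	BAT-25	BAT-26	D5S346	D2S123	D17S250	reported_n_unstable	reported_nci_status	reported_max_pct	reported_score	reported_score_status
14	MSI-H:BRAF-mutant	MSI-H	4	14	0	10	3	4	MSI-H	14	31	MSI-H
24	MSI-H:BRAF-mutant	MSI-H	24	36	0	0	0	2	MSI-H	36	61	MSI-H
25	MSI-H:BRAF-mutant	MSI-H	7	20	0	0	0	2	MSI-H	20	26	MSI-H
29	MSI-H:BRAF-mutant	MSI-H	2	4	0	0	0	1	MSI-L	4	6	MSI-H
31	MSI-H:BRAF-mutant	MSI-H	16	41	0	0	3	3	MSI-H	41	60	MSI-H
32	MSI-H:BRAF-mutant	MSI-H	5	0	3	0	0	2	MSI-H	5	8	MSI-H
34	MSI-H:BRAF-mutant	MSI-H	0	0	0	0	0	0	MSS	0	0	MSS
35	MSI-H:BRAF-mutant	MSI-H	11	0	9	0	0	2	MSI-H	11	20	MSI-H
38	MSI-H:BRAF-mutant	MSI-H	13	34	12	0	0	3	MSI-H	34	59	MSI-H
42	MSI-H:BRAF-mutant	MSI-H	16	28	9	5	0	4	MSI-H	28	58	MSI-H
47	MSI-H:BRAF-mutant	MSI-H	25	38	9	0	4	4	MSI-H	38	76	MSI-H
52	MSI-H:BRAF-mutant	MSI-H	0	11	0	0	5	2	MSI-H	11	16	MSI-H
55	MSI-H:BRAF-mutant	MSI-H	7	54	3	0	8	4	MSI-H	54	71	MSI-H
45	MSI-H:BRAF-mutant	MSI-H	0	5	0	2	0	1	MSI-L	5	7	MSI-H
142	MSI-H:BRAF-mutant	MSI-H	3	7	5	0	7	3	MSI-H	7	21	MSI-H
252	MSI-H:BRAF-mutant	MSI-H	0	8	7	0	0	2	MSI-H	8	14	MSI-H
422	MSI-H:BRAF-mutant	MSI-H	0	0	0	67	0	1	MSI-L	67	67	MSI-H
242	MSI-H:BRAF-mutant	MSI-H	2	12	6	0	0	3	MSI-H	12	20	MSI-H
1	MSI-H:BRAF-wild-type	MSI-H	12	5	4	0	5	4	MSI-H	12	25	MSI-H
2	MSI-H:BRAF-wild-type	MSI-H	5	6	0	0	2	2	MSI-H	6	13	MSI-H
8	MSI-H:BRAF-wild-type	MSI-H	24	22	9	0	6	4	MSI-H	24	61	MSI-H
9	MSI-H:BRAF-wild-type	MSI-H	4	0	0	0	9	2	MSI-H	9	13	MSI-H
16	MSI-H:BRAF-wild-type	MSI-H	0	0	0	0	0	0	MSS	0	0	MSS
17	MSI-H:BRAF-wild-type	MSI-H	0	0	0	6	0	1	MSI-L	6	6	MSI-H
18	MSI-H:BRAF-wild-type	MSI-H	0	4	3	0	0	2	MSI-H	4	7	MSI-H
27	MSI-H:BRAF-wild-type	MSI-H	0	5	0	0	0	1	MSI-L	5	5	MSI-L
40	MSI-H:BRAF-wild-type	MSI-H	2	0	3	0	0	1	MSI-L	3	5	MSI-L
46	MSI-H:BRAF-wild-type	MSI-H	4	0	0	0	4	2	MSI-H	4	8	MSI-H
56	MSI-H:BRAF-wild-type	MSI-H	3	0	2	0	0	1	MSI-L	3	5	MSI-L
58	MSI-H:BRAF-wild-type	MSI-H	0	5	0	4	5	3	MSI-H	5	13	MSI-H
63	MSI-H:BRAF-wild-type	MSI-H	10	2	0	0	5	2	MSI-H	10	17	MSI-H
64	MSI-H:BRAF-wild-type	MSI-H	5	26	8	0	0	3	MSI-H	26	39	MSI-H
72	MSI-H:BRAF-wild-type	MSI-H	0	0	0	4	0	1	MSI-L	4	4	MSI-L
152	MSI-H:BRAF-wild-type	MSI-H	2	2	8	0	0	1	MSI-L	8	12	MSI-H
172	MSI-H:BRAF-wild-type	MSI-H	14	0	4	0	0	2	MSI-H	14	18	MSI-H
232	MSI-H:BRAF-wild-type	MSI-H	0	0	4	0	9	2	MSI-H	9	13	MSI-H
272	MSI-H:BRAF-wild-type	MSI-H	0	0	0	0	0	0	MSS	0	0	MSS
3	MSS	MSS	8	11	0	4	0	3	MSI-H	11	24	MSI-H
4	MSS	MSS	0	0	0	0	0	0	MSS	0	0	MSS
5	MSS	MSS	0	0	0	0	0	0	MSS	0	0	MSS
11	MSS	MSS	0	0	0	0	0	0	MSS	0	0	MSS
15	MSS	MSS	0	2	0	0	0	0	MSS	2	2	MSS
19	MSS	MSS	4	0	0	0	0	1	MSI-L	4	4	MSI-L
21	MSS	MSS	0	0	0	0	5	1	MSI-L	5	5	MSI-L
28	MSS	MSS	1	0	0	1	1	0	MSS	1	4	MSI-L
33	MSS	MSS	0	0	0	0	0	0	MSS	0	0	MSS
48	MSS	MSS	0	0	0	0	3	1	MSI-L	3	3	MSI-L
50	MSS	MSS	0	0	4	0	0	1	MSI-L	4	4	MSI-L
61	MSS	MSS	0	3	0	0	0	1	MSI-L	3	3	MSI-L
65	MSS	MSS	0	0	0	0	0	0	MSS	0	0	MSS
67	MSS	MSS	15	10	0	0	4	3	MSI-H	15	28	MSI-H
69	MSS	MSS	6	0	0	0	4	2	MSI-H	6	9	MSI-H
70	MSS	MSS	0	2	0	0	0	0	MSS	2	2	MSS
71	MSS	MSS	0	0	0	0	0	0	MSS	0	0	MSS
522	MSS	MSS	0	0	0	0	0	0	MSS	0	0	MSS
712	MSS	MSS	0	0	0	0	0	0	MSS	0	0	MSS
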