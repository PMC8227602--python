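sample_id	msih_fraction	BAT-25	BAT-26	D5S346	D2S123	D17S250	reported_n_unstable	reported_nci_status	reported_max_pct	reported_score	reported_score_status
RKO100	1.00	7	0	36	0	13	3	MSI-H	36	56	MSI-H
RKO080	0.80	42	7	23	0	0	3	MSI-H	42	73	MSI-H
RKO060	0.60	11	0	21	6	8	4	MSI-H	21	46	MSI-H
RKO040	0.40	11	0	18	0	22	3	MSI-H	22	51	MSI-H
RKO020	0.20	6	0	17	0	35	3	MSI-H	35	58	MSI-H
RKO010	0.10	0	5	3	0	17	3	MSI-H	17	25	MSI-H
RKO005	0.05	10	0	0	0	18	2	MSI-H	18	29	MSI-H
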