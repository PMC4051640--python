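case	task	vol_tb	vol_aroi	vol_froi	vol_ica	alpha_aroi	beta_aroi	alpha_froi	beta_froi	alpha_ica	beta_ica
1	hand	8.3	7.0	2.6	11.2	0.54	0.64	0.26	0.86	0.95	0.71
2	hand	8.1	8.4	6.6	10.2	0.26	0.26	0.34	0.42	0.27	0.22
3	hand	6.5	-	-	14.2	-	-	-	-	0.06	0.03
4	hand	9.7	1.1	2.9	16.6	0.03	0.29	0.27	0.90	0.68	0.40
5	hand	5.7	21.6	12.1	11.2	0.87	0.23	0.78	0.37	0.69	0.35
6	hand	7.9	-	-	-	-	-	-	-	-	-
7	hand	7.4	5.2	3.2	10.8	0.10	0.15	0.35	0.83	0.62	0.43
8	hand	7.7	4.6	2.9	10.8	0.12	0.19	0.08	0.21	0.23	0.17
9	hand	5.3	17.6	15.0	15.7	0.81	0.24	0.75	0.27	0.81	0.27
10	hand	4.3	3.4	-	-	0.22	0.28	-	-	-	-
11	hand	6.7	17.1	16.3	7.1	0.72	0.28	0.76	0.31	0.38	0.36
12	hand	5.8	25.9	6.8	10.4	0.93	0.21	0.68	0.59	0.11	0.06
13	hand	7.4	6.6	1.5	15.3	0.14	0.16	0.06	0.32	0.00	0.00
7	foot	3.1	7.4	3.5	5.5	0.73	0.30	0.60	0.54	0.63	0.35
9	foot	3.7	4.4	4.2	3.1	0.54	0.46	0.44	0.39	0.39	0.46
10	foot	-	8.1	2.7	-	- -	- -	- -	- -	-	-
11	foot	2.7	4.5	5.3	0.8	0.52	0.31	0.56	0.28	0.04	0.14
12	foot	2.4	8.9	6.0	0.3	0.90	0.24	0.78	0.31	0.09	0.68
13	foot	10.3	9.0	3.5	2.4	0.31	0.36	0.18	0.54	0.11	0.48
8	mouth	8.8	10.5	4.6	10.8	0.41	0.34	0.41	0.77	0.58	0.47
10	mouth	6.0	8.4	-	-	0.08	0.05	-	-	-	-
13	mouth	14.1	8.0	11.1	15.3	0.33	0.58	0.40	0.52	0.49	0.45
7	hand_stim	6.6	1.4	3.5	10.8	0.10	0.48	0.45	0.85	0.65	0.39
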