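case	task	vol_tb	vol_aroi	vol_froi	vol_ica	alpha_aroi	beta_aroi	alpha_froi	beta_froi	alpha_ica	beta_ica
1	hand	6.8	12.6	12.4	4.3	0.85	0.45	0.84	0.46	0.58	0.91
2	hand	8.9	14.6	8.6	8.7	0.47	0.29	0.40	0.41	0.24	0.25
3	hand	10.0	-	-	4.9	-	-	-	-	0.10	0.20
4	hand	8.6	10.8	6.2	8.1	0.44	0.35	0.54	0.75	0.43	0.46
5	hand	5.9	10.2	4.9	5.0	0.64	0.37	0.50	0.60	0.41	0.49
6	hand	6.2	-	-	-	-	-	-	-	-	-
7	hand	8.8	15.2	6.9	11.4	0.37	0.21	0.51	0.65	0.61	0.47
8	hand	6.4	9.0	8.2	5.5	0.25	0.18	0.25	0.19	0.07	0.09
9	hand	4.5	13.8	14.7	3.7	0.75	0.25	0.78	0.24	0.33	0.40
10	hand	4.0	7.5	-	-	0.50	0.27	-	-	-	-
11	hand	3.2	9.6	9.7	9.5	0.59	0.19	0.73	0.24	0.75	0.25
12	hand	4.9	15.6	4.9	3.3	0.87	0.27	0.60	0.59	0.00	0.00
13	hand	9.4	6.9	7.2	3.7	0.17	0.22	0.32	0.41	0.00	0.00
7	foot	3.5	5.9	2.8	5.0	0.64	0.38	0.47	0.59	0.55	0.39
9	foot	8.3	3.2	2.3	3.3	0.26	0.68	0.20	0.70	0.26	0.65
10	foot	-	3.2	4.4	-	- -	- -	- -	- -	-	-
11	foot	6.0	2.7	1.2	1.9	0.26	0.57	0.14	0.70	0.18	0.55
12	foot	7.3	3.3	4.9	0.8	0.30	0.67	0.43	0.64	0.08	0.72
13	foot	18.3	9.0	8.0	1.2	0.27	0.55	0.27	0.61	0.06	0.89
8	mouth	4.6	6.0	2.3	5.5	0.46	0.35	0.44	0.86	0.52	0.43
10	mouth	8.6	5.9	-	-	0.06	0.09	-	-	-	-
13	mouth	27.6	10.4	4.8	3.7	0.30	0.81	0.13	0.73	0.09	0.67
7	hand_stim	6.5	2.3	6.8	11.4	0.15	0.41	0.70	0.67	0.66	0.38
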