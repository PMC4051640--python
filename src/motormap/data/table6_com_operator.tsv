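case	task	d_tb_aroi	d_tb_froi	d_tb_ica	dles_tb	dles_aroi	dles_froi	dles_ica
1	hand	2.0	2.8	0.0	36.7	35.8	37.6	36.7
2	hand	14.6	9.2	13.4	43.2	35.0	36.8	34.1
3	hand	-	-	37.7	30.6	-	-	47.7
4	hand	21.3	4.5	7.5	39.0	21.9	37.7	32.7
5	hand	4.0	2.0	2.8	35.4	31.6	36.1	33.6
6	hand	-	-	-	29.7	-	-	-
7	hand	10.0	6.0	6.6	28.7	26.2	23.7	25.1
8	hand	2.8	4.5	21.0	51.6	50.2	50.4	34.4
9	hand	15.7	16.4	14.0	34.2	41.7	43.4	41.3
10	hand	16.7	-	-	23.2	30.6	-	-
11	hand	16.4	15.7	16.6	34.1	45.4	44.2	45.7
12	hand	9.2	4.9	36.1	22.2	26.7	20.5	52.5
13	hand	8.5	6.3	33.3	19.8	14.7	14.1	50.9
7	foot	3.5	4.9	4.9	36.1	32.8	32.9	32.2
9	foot	10.8	13.1	14.1	41.1	34.2	33.8	33.3
10	foot	- -	- -	-	-	32.2	34.1	-
11	foot	10.2	8.9	15.7	27.0	22.4	21.0	21.4
12	foot	10.8	10.8	15.4	14.7	9.2	9.2	14.6
13	foot	8.9	8.2	12.8	27.5	20.1	22.1	38.3
8	mouth	16.2	6.0	2.0	34.2	47.2	31.9	34.4
10	mouth	26.3	-	-	44.7	38.8	-	-
13	mouth	6.6	7.5	7.5	49.1	45.1	50.9	50.9
7	hand_stim	11.5	2.8	6.3	26.9	33.3	26.3	25.1
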