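case	point	x_mm	y_mm	z_mm	response	d_tb	d_aroi	d_froi	d_ica
3	1	22	-24	74	hand	4.5	-	-	38
3	2	20	-18	78	hand	2.8	-	-	41.4
6	1	-36	-20	68	hand	2	-	-	-
8	1	64	-4	28	mouth	3.4	2	2	0
10	1	40	-26	66	hand	4.9	4.5	-	-
10	2	40	-14	64	hand	6.6	4	-	-
11	1	-28	-16	72	hand	4.8	4.5	4.9	2.8
12	1	-40	-22	68	hand	2	2	2	30.8
12	2	-2	-24	68	foot	0	0	0	7.2
13	1	42	-10	64	hand	2	5.7	8.2	24.5
13	2	40	-10	64	hand	0	4.5	7.4	26
13	3	12	-22	78	foot	2	4	4	16.5
13	4	16	-18	76	foot	2	4	4	16.5
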