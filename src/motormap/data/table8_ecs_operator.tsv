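case	point	x_mm	y_mm	z_mm	response	d_tb	d_aroi	d_froi	d_ica
3	1	22	-24	74	hand	0	-	-	17.9
3	2	20	-18	78	hand	0	-	-	20.4
6	1	-36	-20	68	hand	0	-	-	-
8	1	64	-4	28	mouth	2	2	2	0
10	1	40	-26	66	hand	4.9	7.2	-	-
10	2	40	-14	64	hand	6	4	-	-
11	1	-28	-16	72	hand	2	0	0	2.8
12	1	-40	-22	68	hand	0	0	0	2
12	2	-2	-24	68	foot	6.3	0	0	8.2
13	1	42	-10	64	hand	2	5.7	14.1	2
13	2	40	-10	64	hand	0	4.5	12.8	4
13	3	12	-22	78	foot	0	4	4.9	11.8
13	4	16	-18	76	foot	0	0	0	14.1
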