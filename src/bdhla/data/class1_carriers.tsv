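# Class I (HLA-A, -B, -C) carrier counts, Thai Behcet's disease case-control cohort
# n_case=56 n_control=192; printed_* columns are the values as published
# (OR/CI truncated at 3 dp, p rounded); "-" marks values published as dashes.
# note flags: misprint_ci_high / misprint_stats = published statistic is
# arithmetically inconsistent with the row's own carrier counts;
# printed_undefined = dashes published despite nonzero counts in both groups.
gene	allele	control_carriers	case_carriers	printed_or	printed_p	printed_ci_low	printed_ci_high	note
A	A*01:01:01	10	1	0.330	0.297	0.041	2.642
A	A*02:01:01	12	3	0.849	0.805	0.2310	3.120
A	A*02:01:13	1	0	-	-	-	-
A	A*02:03:01	31	9	0.995	0.989	0.442	2.235
A	A*02:06:01	5	0	-	-	-	-
A	A*02:07:01	35	13	1.356	0.407	0.659	2.787
A	A*02:09:01	1	1	3.472	0.381	0.213	56.425
A	A*02:11:01	1	1	3.472	0.381	0.213	56.425
A	A*02:17:02	1	0	-	-	-	-
A	A*03:01:01	9	0	-	-	-	-
A	A*03:08:01	0	1	-	-	-	-
A	A*11:01:01	82	22	0.868	0.648	0.472	1.593
A	A*11:01:75	0	1	-	-	-	-
A	A*11:01:82	1	0	-	-	-	-
A	A*11:02:01	8	0	-	-	-	-
A	A*23:01:01	1	0	-	-	-	-
A	A*24:02:01	43	16	1.386	0.341	0.708	2.713
A	A*24:02:40	3	0	-	-	-	-
A	A*24:03:01	4	1	0.854	0.889	0.093	7.803
A	A*24:07:01	13	3	0.779	0.705	0.214	2.837
A	A*24:10:01	7	4	2.032	0.272	0.572	7.213
A	A*24:20:01	4	1	0.854	0.889	0.093	7.803
A	A*26:01:01	8	7	3.285	0.028	1.135	9.504
A	A*29:01:01	2	1	1.727	0.658	0.153	19.408
A	A*30:01:01	10	4	1.400	0.583	0.421	4.647
A	A*30:01:12	1	0	-	-	-	-
A	A*31:01:02	4	1	0.854	0.889	0.093	1.803	misprint_ci_high
A	A*32:01:01	3	1	1.145	0.907	0.116	11.232
A	A*33:01:01	1	0	-	-	-	-
A	A*33:03:01	49	15	1.067	0.849	0.543	2.096
A	A*34:01:01	1	0	-	-	-	-
A	A*68:01:01	2	0	-	-	-	-
A	A*68:01:02	1	0	-	-	-	-
A	A*74:02:01	5	1	0.679	0.727	0.0777	5.943
B	B*07:02:01	12	2	0.555	0.451	0.120	2.559
B	B*07:05:01	2	0	-	-	-	-
B	B*08:01:01	1	0	-	-	-	-
B	B*13:01:01	15	6	1.416	0.494	0.522	3.839
B	B*13:02:01	9	4	1.564	0.471	0.462	5.284
B	B*15:01:01	7	1	0.480	0.497	0.057	3.990
B	B*15:02:01	33	7	0.688	0.403	0.286	1.653
B	B*15:07:01	0	2	-	-	-	-
B	B*15:11:01	2	0	-	-	-	-
B	B*15:12:02	4	0	-	-	-	-
B	B*15:15:01	1	0	-	-	-	-
B	B*15:18:01	3	0	-	-	-	-
B	B*15:21:01	1	0	-	-	-	-
B	B*15:25:01	4	2	1.740	0.529	0.310	9.761
B	B*15:32:01	2	0	-	-	-	-
B	B*18:01:01	16	6	1.320	0.582	0.490	3.550
B	B*27:04:01	14	3	0.719	0.616	0.199	2.599
B	B*27:05:02	2	0	-	-	-	-
B	B*35:01:01	5	0	-	-	-	-
B	B*35:03:01	4	0	-	-	-	-
B	B*35:05:01	8	1	0.418	0.416	0.051	3.416
B	B*37:01:01	7	0	-	-	-	-
B	B*38:02:01	13	1	0.250	0.187	0.032	1.956
B	B*39:01:01	3	5	6.176	0.015	1.428	26.712
B	B*39:09:01	2	2	3.518	0.214	0.484	25.563
B	B*40:01:02	31	9	0.994	0.989	0.442	2.235
B	B*40:02:01	9	2	0.753	0.722	0.157	3.590
B	B*40:06:01	7	1	0.480	0.497	0.057	3.990
B	B*44:02:01	0	2	-	-	-	-
B	B*44:03:01	0	1	-	-	-	-
B	B*44:03:02	24	10	1.521	0.308	0.679	3.409
B	B*46:01:01	46	14	1.057	0.873	0.530	2.108
B	B*46:01:19	0	1	-	-	-	-
B	B*48:01:01	5	0	-	-	-	-
B	B*50:01:01	0	1	-	-	-	-
B	B*51:01:01	10	8	3.033	0.027	1.135	8.103
B	B*51:01:02	3	5	6.176	0.015	1.428	26.712
B	B*51:02:01	5	0	-	-	-	-
B	B*51:02:02	1	1	3.472	0.381	0.213	56.425
B	B*51:06:01	1	0	-	-	-	-
B	B*52:01:01	10	2	0.674	0.618	0.1431	3.170
B	B*53:01:01	1	0	-	-	-	-
B	B*54:01:01	6	1	0.563	0.599	0.066	4.782
B	B*55:01:01	5	1	0.679	0.727	0.077	5.943
B	B*55:02:01	2	0	-	-	-	-
B	B*56:01:01	4	2	1.740	0.529	0.310	9.761
B	B*57:01:01	6	2	1.148	0.868	0.225	5.852
B	B*58:01:01	22	4	0.594	0.358	0.195	1.803
B	B*67:01:01	1	0	-	-	-	-
C	C*01:02:01	54	19	1.312	0.403	0.694	2.479
C	C*02:02:02	2	0	-	-	-	-
C	C*03:02:02	23	4	0.565	0.312	0.186	1.708
C	C*03:03:01	12	2	0.555	0.451	0.120	2.559
C	C*03:04:01	25	11	1.632	0.219	0.747	3.568
C	C*04:01:01	21	1	0.148	0.065	0.019	1.126
C	C*04:03:01	8	4	1.769	0.367	0.512	6.108
C	C*04:06:01	3	0	-	-	-	-
C	C*05:01:01	0	2	-	-	-	-
C	C*06:02:01	20	4	0.661	0.469	0.216	2.022
C	C*07:01:01	2	1	1.727	0.658	0.153	19.408
C	C*07:02:01	54	17	1.113	0.745	0.581	2.135
C	C*07:02:99	1	0	-	-	-	-
C	C*07:04:01	15	6	1.416	0.494	0.522	3.839
C	C*07:06:01	26	8	1.064	0.887	0.452	2.502
C	C*07:18:01	0	1	-	-	-	-
C	C*08:01:01	36	7	0.619	0.280	0.259	1.478
C	C*08:22:01	4	1	0.854	0.889	0.093	7.803
C	C*12:02:02	12	2	0.555	0.451	0.120	2.559
C	C*12:03:01	10	0	-	-	-	-
C	C*14:02:01	10	9	3.485	0.010	1.339	9.065
C	C*15:02:01	20	6	1.032	0.949	0.393	2.709
C	C*15:05:02	2	0	-	-	-	-
C	C*18:02:01	1	0	-	-	-	-
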