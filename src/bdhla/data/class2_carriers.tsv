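# Class II (HLA-DPB1, -DRB1, -DQB1) carrier counts, Thai Behcet's disease case-control cohort
# n_case=56 n_control=192; same conventions and note flags as class1_carriers.tsv.
gene	allele	control_carriers	case_carriers	printed_or	printed_p	printed_ci_low	printed_ci_high	note
DPB1	DPB1*01:01:01	9	4	1.564	0.471	0.462	5.284
DPB1	DPB1*02:01:02	53	12	0.715	0.357	0.350	1.458
DPB1	DPB1*02:02:01	26	10	1.387	0.421	0.624	9.086	misprint_ci_high
DPB1	DPB1*03:01:01	26	6	0.766	0.580	0.298	1.965
DPB1	DPB1*04:01:01	37	7	0.598	0.247	0.250	1.427
DPB1	DPB1*04:02:01	20	3	0.486	0.260	0.139	1.702
DPB1	DPB1*05:01:01	71	30	1.966	0.028	1.077	3.587
DPB1	DPB1*06:01:01	1	0	-	-	-	-
DPB1	DPB1*09:01:01	9	1	0.369	0.350	0.045	2.982
DPB1	DPB1*10:01:01	5	0	-	-	-	-
DPB1	DPB1*13:01:01	48	16	1.200	0.591	0.616	2.334
DPB1	DPB1*14:01:01	15	1	0.214	0.140	0.027	1.661
DPB1	DPB1*16:01:01	1	2	-	-	-	-	printed_undefined
DPB1	DPB1*17:01:01	8	5	2.254	0.169	0.707	7.190
DPB1	DPB1*19:01:01	3	2	2.333	0.360	0.380	14.323
DPB1	DPB1*21:01	6	3	1.754	0.437	0.424	7.252
DPB1	DPB1*22:01:01	3	1	1.145	0.907	0.116	11.232
DPB1	DPB1*23:01:01	0	1	-	-	-	-
DPB1	DPB1*26:01:02	4	2	1.740	0.529	0.310	9.761
DPB1	DPB1*31:01:01	4	1	0.854	0.889	0.093	7.803
DPB1	DPB1*34:01:01	1	0	-	-	-	-
DPB1	DPB1*38:01	0	1	-	-	-	-
DPB1	DPB1*39:01:01	3	0	-	-	-	-
DPB1	DPB1*47:01:01	3	0	-	-	-	-
DPB1	DPB1*48:01	1	0	-	-	-	-
DRB1	DRB1*01:01:01	3	0	-	-	-	-
DRB1	DRB1*03:01:01	14	2	0.470	0.329	0.103	2.137
DRB1	DRB1*03:02:01	21	2	0.301	0.113	0.068	1.327
DRB1	DRB1*04:03:01	3	0	-	-	-	-
DRB1	DRB1*04:05:01	2	0	-	-	-	-
DRB1	DRB1*07:01:01	24	10	1.521	0.308	0.679	3.409
DRB1	DRB1*08:02:01	0	2	-	-	-	-
DRB1	DRB1*08:03:02	14	2	0.470	0.329	0.103	2.137
DRB1	DRB1*09:01:02	17	2	0.381	0.207	0.085	1.702
DRB1	DRB1*10:01:01	16	1	0.200	0.123	0.025	1.542
DRB1	DRB1*11:01:01	55	19	1.279	0.448	0.677	2.414
DRB1	DRB1*11:03:01	4	0	-	-	-	-
DRB1	DRB1*11:04:01	2	0	-	-	-	-
DRB1	DRB1*12:01:01	4	2	1.740	0.529	0.310	9.761
DRB1	DRB1*12:02:01	34	15	1.700	0.136	0.846	3.416
DRB1	DRB1*13:01:01	1	1	3.472	0.381	0.213	56.425
DRB1	DRB1*13:02:01	4	1	0.854	0.889	0.093	7.803
DRB1	DRB1*13:07:01	6	0	-	-	-	-
DRB1	DRB1*14:02:01	14	3	0.719	0.616	0.199	2.599
DRB1	DRB1*14:04:01	1	1	3.472	0.381	0.213	56.425
DRB1	DRB1*14:05:01	24	12	1.909	0.099	0.885	4.116
DRB1	DRB1*14:06:01	5	0	-	-	-	-
DRB1	DRB1*14:07:01	1	0	-	-	-	-
DRB1	DRB1*14:54:01	82	33	1.924	0.034	1.051	3.522
DRB1	DRB1*15:01:01	4	0	-	-	-	-
DRB1	DRB1*15:02:01	20	2	0.318	0.131	0.072	1.406
DRB1	DRB1*16:02:01	7	1	0.480	0.497	0.057	3.990
DQB1	DQB1*02:01:01	9	2	0.753	0.722	0.157	3.590
DQB1	DQB1*02:02:01	29	8	0.936	0.880	0.401	2.183
DQB1	DQB1*03:01:01	75	22	1.009	0.976	0.548	1.857
DQB1	DQB1*03:02:01	29	2	0.208	0.036	0.048	0.901
DQB1	DQB1*03:03:02	41	7	0.526	0.145	0.221	1.248
DQB1	DQB1*04:01:01	1	0	-	-	-	-
DQB1	DQB1*04:02:01	16	4	0.846	0.774	0.271	2.641
DQB1	DQB1*05:01:01	20	1	0.156	0.073	0.020	1.191
DQB1	DQB1*05:01:24	29	5	0.551	0.243	0.202	1.497
DQB1	DQB1*05:02:01	57	19	1.216	0.545	0.645	2.292
DQB1	DQB1*05:03:01	16	12	3.000	0.008	1.323	6.798
DQB1	DQB1*06:01:01	23	7	1.049	0.916	0.425	2.591
DQB1	DQB1*06:02:01	3	2	2.333	0.360	0.380	14.323
DQB1	DQB1*06:03:01	2	1	1.727	0.658	0.153	19.408
DQB1	DQB1*06:04:01	1	0	-	-	-	-
DQB1	DQB1*06:09:01	4	2	0.854	0.889	0.093	7.803	misprint_stats
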