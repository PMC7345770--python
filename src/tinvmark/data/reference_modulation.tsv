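set_name	gene	affymetrix_id	codelink_id	call_1d	call_3d	call_1w	time_invariant
consensus_1d	A2m	1367794_at	NM_012488	-	-	-	Yes
consensus_1d	Ca3	1386977_at	NM_019292	-	-	-	Yes
consensus_1d	Cxcl1	1387316_at	NM_030845	-	-	-	Yes
consensus_1d	Cyp8b1	1368435_at	NM_031241	-	-	+/-	No
consensus_3d	A2m	1367794_at	NM_012488	-	-	-	Yes
consensus_3d	Akr7a3	1368121_at	NM_013215	+	+	+	Yes
consensus_3d	Aqp7	1368317_at	NM_019157	+	+	+	Yes
consensus_3d	Ca3	1386977_at	NM_019292	-	-	-	Yes
consensus_3d	Cdc2a	1367776_at	NM_019296	+	+	+	Yes
consensus_3d	Cdkn3	1372685_at	BE113362	+	+	+	Yes
consensus_3d	Cyp2c11	1387328_at	NM_019184	-	-	-	Yes
consensus_3d	Ntf3	1387267_at	NM_031073	-	-	-	Yes
consensus_3d	Sds	1369864_a_at	NM_053962	-	-	-	Yes
consensus_1w	Akr7a3	1368121_at	NM_013215	+	+	+	Yes
consensus_1w	Aqp7	1368317_at	NM_019157	+	+	+	Yes
consensus_1w	Atf3	1369268_at	NM_012912	+	+/-	+	No
consensus_1w	beta-sarcoglycan	1374796_at	AI413058	+	+	+	Yes
consensus_1w	Ca3	1386977_at	NM_019292	-	-	-	Yes
consensus_1w	Cpt1b	1367742_at	NM_013200	+	+	+	Yes
consensus_1w	Cyp2c11	1387328_at	NM_019184	-	-	-	Yes
consensus_1w	Cyp17a1	1387123_at	NM_012753	-	+/-	+	No
consensus_1w	Ntf3	1387267_at	NM_031073	-	-	-	Yes
consensus_1w	RGD1562428_predicted	1376296_at	BF387347	+	+	+	Yes
consensus_1w	Snx10	1383585_at	AI043753	+	+	+	Yes
E5	Abcb4	1369161_at	NA	-	-	-	Yes
E5	Akr7a3	1368121_at	NM_013215	+	+	+	Yes
E5	Ccng1	1367764_at	NM_012923	+	+	+/-	No
E5	Cdkn1a	1387391_at	NM_080782	+	+/-	+/-	No
E5	Phlda3	1375224_at	AW520812	+/-	+/-	+	No
F19	Akr7a3	1368121_at	NM_013215	+	+	+	Yes
F19	Aldh1a1	1387022_at	CK222590	+	+	+	Yes
F19	Anxa2	1367584_at	AA956299	+/-	+	+	No
F19	Btg2	1386994_at	NM_017259	-	+/-	+/-	No
F19	Cdkn1a	1387391_at	NM_080782	+	+/-	+/-	No
F19	Cited4	1390008_at	NM_053699	+/-	+/-	+/-	No
F19	ESTs	NA	BM388029	-	+	+	No
F19	Gpr146	1373158_at	NA	-	-	-	Yes
F19	Ica1	1367787_at	NM_030844	+	+	+	Yes
F19	LitaF	1370928_at	U53184	+/-	+/-	+/-	No
F19	Mat1a	1371031_at	X60822	-	-	-	Yes
F19	Mgmt	1368311_at	NM_012861	+/-	+	+	No
F19	Mt1a	1371237_at	CR458797	-	-	-	Yes
F19	Ppia	1398850_at	BI303474	+/-	+/-	+/-	No
F19	Prodh2	1389645_at	AI058310	-	-	-	Yes
F19	Psmb9	1370186_at	NM_012708	+/-	+/-	+/-	No
F19	Tap1	1388149_at	X57523	+/-	+/-	+/-	No
F19	Trnt1	1383144_at	AI412002	+/-	+/-	+	No
F19	Usp2	1387703_at	NM_053774	+/-	-	+/-	No
U9	Abcb1a	1370583_s_at	NA	+	+	+	Yes
U9	Acot9	1379262_at	NA	+	+	+	Yes
U9	Cd276_1	1395737_at	BF398424	+/-	+/-	+	No
U9	Cd276_2	1374198_at	NA	+/-	+	+	No
U9	Cdh13_1	1375719_s_at	NM_138889	+/-	+/-	+/-	No
U9	Cdh13_2	1373102_at	NA	+/-	+/-	+/-	No
U9	Ica1	1367787_at	NM_030844	+	+	+	Yes
U9	Tes	1383401_at	NM_173132	+	+/-	+/-	No
U9	Tmem184c	1379419_at	NA	+	+	+	Yes
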