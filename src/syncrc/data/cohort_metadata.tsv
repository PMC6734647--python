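patient	sex	age	tumour	location	histology	grade	mmr	tnm	size_cm	adenomas
s894	M	79	s894-1	Descendens	ac	2	MSS	T2N0M0	6	Yes
s894	M	79	s894-2	Descendens	ac in situ	2	MSS	Tis	1.2	Yes
c440	M	83	c440-1	Border of rectosigma	ac in situ	1	MSS	Tis	NA	Yes
c440	M	83	c440-2	Caecum	ac	3	MSI	T3N0M0	4.5	Yes
sync_1	M	82	sync_1-1	Caecum	ac	3	MSS	T2N0M0	3.5	No
sync_1	M	82	sync_1-2	Transversum	ac	3	MSS	T3N0M0	5	No
sync_2	M	82	sync_2-1	Rectum	ac	2	MSS	T4N0M1	4.3	Yes
sync_2	M	82	sync_2-2	Rectum	ac in situ	1	MSS	Tis	NA	Yes
sync_3	F	67	sync_3-1	Rectum	ac	2	MSS	T3N1M0	NA	Yes
sync_3	F	67	sync_3-2	Rectum	ac	2	MSS	T1	NA	Yes
s75	M	71	s75-1	Rectum	ac muc	3	MSS	T3N0M0	4	Yes
s75	M	71	s75-2	Caecum	ac	2	MSS	T3N0M0	5	Yes
s1268	M	66	s1268-1	Ascendens	MANEC	4	MSS	T3N2M0	5.2	Yes
s1268	M	66	s1268-2	Sigma	ac	2	MSS	T3N1M1	4	Yes
s882	F	67	s882-1	Rectum	ac	2	MSS	T1	1	No
s882	F	67	s882-2	Caecum	ac	2	MSS	T4N0M0	2	No
sync_4	M	78	sync_4-1	Ascendens	ac muc	3	MSI	T3N0M0	11	Yes
sync_4	M	78	sync_4-2	Ascendens	ac muc	3	MSI	T3N0M0	8	Yes
s387	M	62	s387-1	Flexura lienalis	ac	1	MSS	T3N1M1	3.5	NA
s387	M	62	s387-2	Flexura lienalis	ac	1	MSS	T3N1M1	8	NA
sync_6	M	72	sync_6-1	Caecum	ac	2	MSS	T4N1M0	4.1	Yes
sync_6	M	72	sync_6-2	Ascendens	ac	2	MSS	T2N0M0	4.7	Yes
s483	F	81	s483-1	Caecum	ac muc	3	MSI	T3N2M0	9	Yes
s483	F	81	s483-2	Ascendens	ac	1	MSI	T1	1.5	Yes
s956	M	76	s956-1	Rectum	ac	2	MSS	T3N1M0	6	Yes
s956	M	76	s956-2	Sigma	ac	2	MSS	T3N1M0	4	Yes
s404	M	61	s404-1	Sigma	ac	2	MSS	T1N1M0	3.4	Yes
s404	M	61	s404-2	Sigma	ac	2	MSS	T2N1M0	5.5	Yes
sync_7	M	72	sync_7-1	Rectum	ac	2	MSS	T2N0M0	4	Yes
sync_7	M	72	sync_7-2	Sigma	ac	2	MSS	T1	4	Yes
sync_9	M	80	sync_9-1	Rectum	ac	2	MSS	T2N0M0	3	Yes
sync_9	M	80	sync_9-2	Sigma	ac	2	MSS	T1	NA	Yes
sync_10	M	59	sync_10-1	Rectum	ac	2	MSS	T3N1M0	4	No
sync_10	M	59	sync_10-2	Sigma	ac	2	MSS	T4N1M0	4.5	No
sync_11	M	48	sync_11-1	Ascendens	ac	2	MSI	T3N0M0	3.8	Yes
sync_11	M	48	sync_11-2	Ascendens	ac	2	MSI	T3N0M0	11	Yes
sync_11	M	48	sync_11-3	Ascendens	ac	2	MSI	T1N0M0	1	Yes
s1036	M	77	s1036-1	Sigma	ac	2	MSS	T4N0M0	12	Yes
s1036	M	77	s1036-2	Sigma	ac	2	MSS	T1N0M0	1.7	Yes
s1283	F	75	s1283-1	Caecum	ac	2	MSI	T3N0M0	3.5	Yes
s1283	F	75	s1283-2	Sigma	ac	NA	MSS	T4N2M0	2.5	Yes
c110	M	49	c110-1	Rectum	ac	2	MSS	T3N0M0	5	Yes
c110	M	49	c110-2	Descendens	ac	2	MSS	T3N0M0	3.2	Yes
c117	F	83	c117-1	Descendens	ac	2	MSS	T3N1M0	7.5	Yes
c117	F	83	c117-2	Rectum	ac	2	MSS	T3N0M0	5	Yes
s934	M	51	s934-1	Rectum	ac	2	MSS	T2N0M0	4	No
s934	M	51	s934-2	Sigma	ac	2	MSS	T3N2M0	5	No
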