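tumour	patient	mmr	CD3_CT	CD3_IM	CD8_CT	CD8_IM
s894-1	s894	MSS	814.2	1137.7	619.3	332.4
s894-2	s894	MSS	676.3	1437.3	736.0	606.0
c440-1	c440	MSS	899.4	1167.7	572.6	145.5
c440-2	c440	MSI	1374.8	1054.1	459.5	472.1
sync_1-1	sync_1	MSS	NA	NA	NA	NA
sync_1-2	sync_1	MSS	NA	NA	NA	NA
sync_2-1	sync_2	MSS	NA	NA	NA	NA
sync_2-2	sync_2	MSS	NA	NA	NA	NA
sync_3-1	sync_3	MSS	948.1	698.7	676.7	328.4
sync_3-2	sync_3	MSS	1391.4	1489.2	632.0	496.4
s75-1	s75	MSS	268.8	345.8	164.3	80.1
s75-2	s75	MSS	789.0	184.9	109.6	209.8
s1268-1	s1268	MSS	1067.1	178.2	127.3	144.8
s1268-2	s1268	MSS	1128.0	1375.2	94.8	43.9
s882-1	s882	MSS	808.7	722.8	91.9	139.7
s882-2	s882	MSS	1260.5	1274.8	532.1	46.2
sync_4-1	sync_4	MSI	400.4	247.0	45.8	39.7
sync_4-2	sync_4	MSI	1439.3	756.6	494.8	666.6
s387-1	s387	MSS	NA	NA	NA	NA
s387-2	s387	MSS	NA	NA	NA	NA
sync_6-1	sync_6	MSS	622.2	1327.6	331.0	61.5
sync_6-2	sync_6	MSS	629.5	955.3	329.5	597.4
s483-1	s483	MSI	1370.2	871.9	579.5	108.2
s483-2	s483	MSI	1226.4	877.1	440.1	434.8
s956-1	s956	MSS	1091.4	281.9	29.2	33.2
s956-2	s956	MSS	896.7	1331.1	686.7	87.9
s404-1	s404	MSS	1371.3	1371.2	593.4	534.2
s404-2	s404	MSS	1055.1	115.7	35.0	33.8
sync_7-1	sync_7	MSS	178.9	181.8	122.2	180.3
sync_7-2	sync_7	MSS	1188.2	957.9	191.3	53.8
sync_9-1	sync_9	MSS	89.1	417.8	115.5	181.8
sync_9-2	sync_9	MSS	734.2	660.8	450.7	745.2
sync_10-1	sync_10	MSS	133.1	300.7	54.7	87.3
sync_10-2	sync_10	MSS	1002.8	853.0	697.2	352.0
sync_11-1	sync_11	MSI	1447.4	1024.2	659.4	485.0
sync_11-2	sync_11	MSI	1447.8	796.3	696.0	409.8
sync_11-3	sync_11	MSI	623.7	1115.2	192.3	95.6
s1036-1	s1036	MSS	302.4	227.1	149.3	102.4
s1036-2	s1036	MSS	1463.4	922.2	492.1	447.8
s1283-1	s1283	MSI	994.2	1027.9	626.2	59.7
s1283-2	s1283	MSS	1233.4	1328.2	551.1	85.3
c110-1	c110	MSS	948.1	1026.3	69.0	112.0
c110-2	c110	MSS	1143.8	1156.7	694.5	348.7
c117-1	c117	MSS	701.9	718.3	173.5	153.3
c117-2	c117	MSS	1092.8	1133.5	340.0	605.7
s934-1	s934	MSS	NA	NA	NA	NA
s934-2	s934	MSS	NA	NA	NA	NA
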