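name	unigene	bud	flower	leaf	root	seed	silique	whole_plant	unspecified_tissue	other
BrnsLtpI.1	Bra.119	2180	856	1724	349	949	4151	y	y	y
BrnsLtpI.2	Bra.1471	363	0	172	279	0	125	y	y	y
BrnsLtpI.3	Bra.71	2180	1012	57	0	474	4403	-	-	y
BrnsLtpI.4	Bra.119	2180	856	1724	349	949	4151	y	y	y
BrnsLtpI.5	Bra.13066	-	-	-	-	-	-	-	y	-
BrnsLtpI.6	Bra.13066	-	-	-	-	-	-	-	y	-
BrnsLtpI.7	Bra.8616	2604	1869	0	0	0	0	y	y	-
BrnsLtpI.8	Bra.71	2180	1012	57	0	474	4403	-	-	y
BrnsLtpI.9	Bra.1589	0	233	574	139	0	880	y	y	y
BrnsLtpI.10	Bra.9345	0	0	57	0	0	3270	y	-	-
BrnsLtpI.11	Bra.293	121	311	57	0	0	2390	-	-	y
BrnsLtpI.12	Bra.18420	0	0	57	0	0	0	-	-	y
BrnsLtpI.13	Bra.10478	0	0	57	0	0	1509	-	y	y
BrnsLtpI.14	Bra.148	121	4985	57	0	0	1635	-	y	-
BrnsLtpI.15	Bra.3744	0	0	114	69	0	0	y	y	y
BrnsLtpI.16	Bra.1371	5390	4907	0	0	0	0	-	y	-
BrnsLtpI.17	Bra.17303	0	0	0	698	0	0	-	-	y
BrnsLtpI.18	Bra.1371	5390	4907	0	0	0	0	-	y	-
BrnsLtpI.19	Bra.9008	0	389	57	0	0	0	-	-	-
BrnsLtpII.1	-	-	-	-	-	-	-	-	-	-
BrnsLtpII.2	Bra.11434	-	-	-	-	-	-	-	y	-
BrnsLtpII.3	Bra.17924	0	311	0	69	0	0	y	-	y
BrnsLtpII.4	-	-	-	-	-	-	-	-	-	-
BrnsLtpII.5	Bra.11200	-	-	-	-	-	-	-	y	-
BrnsLtpII.6	Bra.4920	0	311	57	628	0	251	y	-	y
BrnsLtpII.7	Bra.4920	0	311	57	628	0	251	y	-	y
BrnsLtpII.8	-	-	-	-	-	-	-	-	-	-
BrnsLtpII.9	Bra.11200	-	-	-	-	-	-	-	y	-
BrnsLtpII.10	Bra.11200	-	-	-	-	-	-	-	y	-
BrnsLtpII.11	Bra.6760	-	-	-	-	-	-	-	y	-
BrnsLtpII.12	Bra.11434	-	-	-	-	-	-	-	y	-
BrnsLtpII.13	Bra.17924	0	311	0	69	0	0	y	-	y
BrnsLtpII.14	Bra.11101	-	-	-	-	-	-	-	y	-
BrnsLtpII.15	Bra.503	1635	2336	0	0	0	0	-	-	-
BrnsLtpIII.1	Bra.21209	1453	233	0	0	0	0	-	-	-
BrnsLtpIII.2	Bra.140	302	0	0	0	0	0	-	-	-
BrnsLtpIII.3	Bra.140	302	0	0	0	0	0	-	-	-
BrnsLtpIV.1	-	-	-	-	-	-	-	-	-	-
BrnsLtpIV.2	Bra.2602	0	0	114	0	0	0	y	-	y
BrnsLtpIV.3	Bra.2602	0	0	114	0	0	0	y	-	y
BrnsLtpIV.4	Bra.3442	0	311	229	0	0	251	-	-	-
BrnsLtpIV.5	-	-	-	-	-	-	-	-	-	-
BrnsLtpIV.6	Bra.5092	0	0	0	209	0	0	-	-	-
BrnsLtpIV.7	Bra.12938	0	0	0	0	0	125	-	y	-
BrnsLtpIV.8	Bra.10653	-	-	-	-	-	-	-	y	-
BrnsLtpV.1	Bra.26893	0	0	0	139	0	0	-	-	-
BrnsLtpV.2	Bra.3434	0	0	114	139	0	125	-	-	-
BrnsLtpVI.1	Bra.7258	-	-	-	-	-	-	-	y	-
BrnsLtpVI.2	-	-	-	-	-	-	-	-	-	-
BrnsLtpVI.3	-	-	-	-	-	-	-	-	-	-
BrnsLtpVI.4	-	-	-	-	-	-	-	-	-	-
BrnsLtpVIII.1	-	-	-	-	-	-	-	-	-	-
BrnsLtpIX.1	Bra.25295	0	233	0	0	0	0	-	-	-
BrnsLtpIX.2	Bra.20831	60	0	0	0	0	0	-	-	-
BrnsLtpIX.3	Bra.21558	121	77	0	0	0	0	y	-	-
BrnsLtpXI.1	Bra.31801	-	-	-	-	-	-	-	-	-
BrnsLtpXI.2	Bra.30903	0	0	57	0	0	0	-	-	-
BrnsLtpXI.3	Bra.10370	-	-	y	-	-	-	-	-	y
BrnsLtpXI.4	Bra.18420	0	0	57	0	0	0	-	-	y
BrnsLtpXI.5	Bra.18420	0	0	57	0	0	0	-	-	y
BrnsLtpXI.6	Bra.18420	0	0	57	0	0	0	-	-	y
BrnsLtpY.1	Bra.389	181	77	0	0	0	0	-	-	-
BrnsLtpY.2	Bra.7621	-	-	-	-	-	-	-	y	-
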