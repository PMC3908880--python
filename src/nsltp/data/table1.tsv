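name	locus	chromosome	start	end	strand	introns	ecm	sp_len	mp_len	mm	pi	type	tandem
BrnsLtpI.1	Bra000068	A03	9142369	9142755	+	none	C-X9-C-X13-CC-X19-CXC-X21-C-X13-C	25	103	10723.34	10.26	I	0
BrnsLtpI.2	Bra001345	A03	15944546	15944887	+	none	C-X9-C-X14-CC-X19-CXC-X24-C-X13-C	20	93	9651.88	10.28	I	0
BrnsLtpI.3	Bra005098	A05	3409556	3410188	-	228	C-X9-C-X13-CC-X19-CXC-X23-C-X13-C	18	116	11898.93	11.65	I	1
BrnsLtpI.4	Bra005099	A05	3413125	3413749	-	268	C-X9-C-X14-CC-X19-CXC-X22-C-X13-C	25	93	9414.92	11.08	I	1
BrnsLtpI.5	Bra006721	A03	4792207	4792704	-	150	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	23	92	9175.57	9.53	I	0
BrnsLtpI.6	Bra006736	A03	4845130	4845623	+	116	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	22	103	11229.85	7.31	I	0
BrnsLtpI.7	Bra012848	A03	21927444	21928521	-	718	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	24	95	9922.37	8.05	I	0
BrnsLtpI.8	Bra017112	A04	16558054	16558647	+	237	C-X9-C-X13-CC-X19-CXC-X23-C-X13-C	25	93	9253.68	11.59	I	1
BrnsLtpI.9	Bra017113	A04	16555397	16556028	+	278	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	25	92	9430.85	11.73	I	1
BrnsLtpI.10	Bra020322	A02	6218834	6219334	-	162	C-X9-C-X13-CC-X19-CXC-X19-C-X13-C	23	89	8936.34	9.78	I	1
BrnsLtpI.11	Bra020323	A02	6223820	6224155	+	none	C-X9-C-X14-CC-X19-CXC-X19-C-X13-C	23	88	8849.35	10.00	I	1
BrnsLtpI.12	Bra024983	A06	24518522	24518875	+	none	C-X8-C-X16-CC-X19-CXC-X24-C-X9-C	22	95	10052.28	10.07	I	0
BrnsLtpI.13	Bra029172	A03	6690210	6690542	+	none	C-X9-C-X13-CC-X19-CXC-X19-C-X13-C	23	87	8740.24	10.30	I	0
BrnsLtpI.14	Bra029719	A05	22525095	22525430	+	none	C-X9-C-X13-CC-X19-CXC-X24-C-X13-C	19	92	9535.75	9.82	I	0
BrnsLtpI.15	Bra036788	A09	25812372	25812722	-	none	C-X9-C-X13-CC-X19-CXC-X23-C-X13-C	25	91	9682.25	12.44	I	0
BrnsLtpI.16	Bra036789	A09	25802085	25802778	-	328	C-X9-C-X14-CC-X19-CXC-X23-C-X13-C	24	97	10473.18	8.28	I	0
BrnsLtpI.17	Bra037222	A09	4927969	4928711	+	392	C-X9-C-X14-CC-X19-CXC-X21-C-X13-C	22	94	9413.56	4.52	I	0
BrnsLtpI.18	Bra038907	A01	12636983	12637614	+	272	C-X9-C-X13-CC-X19-CXC-X22-C-X13-C	24	95	9913.47	8.34	I	1
BrnsLtpI.19	Bra038908	A01	12629898	12630245	+	none	C-X9-C-X13-CC-X19-CXC-X23-C-X13-C	24	91	9693.23	12.40	I	1
BrnsLtpII.1	Bra008112	A02	13195464	13195760	+	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	30	68	7645.89	9.26	II	0
BrnsLtpII.2	Bra008375	A02	15167775	15168068	+	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	18	79	8467.68	4.89	II	0
BrnsLtpII.3	Bra014154	A08	2994554	2994847	-	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	29	68	7103.21	10.12	II	0
BrnsLtpII.4	Bra015966	A07	20026923	20027216	+	none	C-X7-C-X13-CC-X8-CXC-X23-C-X5-C	30	67	7626.94	9.58	II	0
BrnsLtpII.5	Bra018687	A06	2603650	2603949	-	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	24	75	8036.32	8.22	II	0
BrnsLtpII.6	Bra021299	A01	22700481	22700774	+	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	29	68	7464.86	12.14	II	0
BrnsLtpII.7	Bra022308	A05	18509672	18509962	-	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	28	68	7411.84	12.02	II	0
BrnsLtpII.8	Bra025378	A06	21876530	21876814	+	none	C-X7-C-X14-CC-X8-CXC-X25-C-X6-C	23	71	7607.87	5.43	II	0
BrnsLtpII.9	Bra027111	A09	8544965	8545258	-	none	C-X7-C-X13-CC-X8-CXC-X21-C-X6-C	24	73	7856.14	5.06	II	1
BrnsLtpII.10	Bra027114	A09	8562465	8562758	-	none	C-X7-C-X13-CC-X8-CXC-X21-C-X6-C	24	73	7972.22	4.86	II	1
BrnsLtpII.11	Bra028162	A04	6295941	6296249	+	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	24	78	8399.71	4.81	II	0
BrnsLtpII.12	Bra030699	A08	20754782	20755075	+	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	24	73	7913.12	4.64	II	0
BrnsLtpII.13	Bra032265	A05	12176382	12176675	-	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	29	68	7233.42	10.38	II	0
BrnsLtpII.14	Bra033084	A02	21491213	21491515	+	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	26	74	7845.08	6.75	II	0
BrnsLtpII.15	Bra040627	A02	9924592	9924879	+	none	C-X7-C-X13-CC-X8-CXC-X23-C-X6-C	21	74	7663.76	8.34	II	0
BrnsLtpIII.1	Bra009282	A10	15963803	15964270	-	177	C-X9-C-X16-CC-X9-CXC-X12-C-X6-C	29	67	6969.07	4.43	III	0
BrnsLtpIII.2	Bra028294	A01	18866657	18866944	-	none	C-X9-C-X16-CC-X9-CXC-X12-C-X6-C	31	64	6730.60	4.90	III	0
BrnsLtpIII.3	Bra029135	A03	6509041	6509295	-	none	C-X9-C-X16-CC-X9-CXC-X12-C-X6-C	20	64	6729.72	6.78	III	0
BrnsLtpIV.1	Bra002906	A10	6849704	6850036	+	none	C-X9-C-X15-CC-X9-CXC-X22-C-X8-C	23	87	9362.02	9.46	IV	1
BrnsLtpIV.2	Bra002907	A10	6843872	6844180	+	none	C-X9-C-X15-CC-X9-CXC-X19-C-X7-C	28	74	7850.28	10.71	IV	1
BrnsLtpIV.3	Bra002914	A10	6777869	6778177	-	none	C-X9-C-X15-CC-X9-CXC-X19-C-X7-C	28	74	7774.18	10.10	IV	0
BrnsLtpIV.4	Bra020696	A02	23700424	23700738	-	none	C-X9-C-X15-CC-X9-CXC-X24-C-X7-C	28	76	7992.20	4.70	IV	0
BrnsLtpIV.5	Bra020839	A08	11767442	11767795	+	none	C-X10-C-X11-CC-X12-CXC-X23-C-X7-C	25	92	9845.14	4.52	IV	0
BrnsLtpIV.6	Bra022364	A05	18159874	18160179	+	none	C-X9-C-X19-CC-X9-CXC-X24-C-X6-C	23	78	8313.64	9.02	IV	0
BrnsLtpIV.7	Bra028980	A03	5697175	5697474	-	none	C-X9-C-X15-CC-X9-CXC-X19-C-X6-C	26	73	7472.52	4.46	IV	0
BrnsLtpIV.8	Bra035573	A02	7465564	7465998	-	72	C-X9-C-X15-CC-X9-CXC-X22-C-X8-C	30	90	9604.48	9.78	IV	0
BrnsLtpV.1	Bra005153	A05	3743608	3744053	-	98	C-X14-C-X14-CC-X12-CXC-X24-C-X10-C	23	92	9521.52	12.31	V	0
BrnsLtpV.2	Bra014853	A04	3607346	3607959	+	224	C-X14-C-X14-CC-X11-CXC-X24-C-X10-C	23	106	11085.73	9.16	V	0
BrnsLtpVI.1	Bra011229	A01	3189969	3190301	-	none	C-X10-C-X16-CC-X9-CXC-X22-C-X9-C	19	91	9647.42	10.20	VI	0
BrnsLtpVI.2	Bra034567	A08	12794464	12794909	-	101	C-X10-C-X17-CC-X9-CXC-X22-C-X9-C	28	86	9277.77	9.89	VI	1
BrnsLtpVI.3	Bra034568	A08	12792882	12793311	-	85	C-X10-C-X17-CC-X9-CXC-X22-C-X9-C	28	86	9285.70	9.82	VI	1
BrnsLtpVI.4	Bra034570	A08	12788663	12789092	-	85	C-X10-C-X17-CC-X9-CXC-X22-C-X9-C	28	86	9285.70	9.82	VI	1
BrnsLtpVIII.1	Bra015984	A07	19946287	19946673	-	none	C-X6-C-X14-CC-X12-CXC-X25-C-X8-C	22	106	11657.72	8.11	VIII	0
BrnsLtpIX.1	Bra001252	A03	15530671	15530955	-	none	C-X13-C-X15-CC-X9-CXC-X22-C-X6-C	17	77	7975.40	6.93	IX	0
BrnsLtpIX.2	Bra006901	A09	26056900	26057265	-	none	C-X13-C-X15-CC-X9-CXC-X22-C-X6-C	24	97	10290.02	4.72	IX	0
BrnsLtpIX.3	Bra012819	A03	22081654	22082025	+	none	C-X13-C-X15-CC-X9-CXC-X22-C-X6-C	26	97	10396.21	4.72	IX	0
BrnsLtpXI.1	Bra000287	A03	10350000	10350350	+	none	C-X9-C-X18-CC-X13-CXC-X24-C-X9-C	29	87	9167.88	6.86	XI	0
BrnsLtpXI.2	Bra018483	A05	8507982	8508317	+	none	C-X9-C-X20-CC-X13-CXC-X24-C-X9-C	23	88	9021.55	4.35	XI	0
BrnsLtpXI.3	Bra018544	A05	9107060	9107431	-	none	C-X9-C-X18-CC-X13-CXC-X25-C-X9-C	26	97	10165.23	9.81	XI	0
BrnsLtpXI.4	Bra024980	A06	24509174	24509509	+	none	C-X8-C-X16-CC-X13-CXC-X24-C-X9-C	22	89	9465.57	10.35	XI	1
BrnsLtpXI.5	Bra024981	A06	24511564	24511899	+	none	C-X8-C-X16-CC-X13-CXC-X24-C-X9-C	22	89	9465.57	10.35	XI	1
BrnsLtpXI.6	Bra024982	A06	24516109	24516444	+	none	C-X8-C-X16-CC-X13-CXC-X24-C-X9-C	22	89	9465.57	10.35	XI	1
BrnsLtpY.1	Bra024207	A03	26879106	26879879	+	242,106	C-X9-C-X14-CC-X30-CXC-X23-C-X13-C	21	120	13391.43	5.33	Y	0
BrnsLtpY.2	Bra040156	A01	4374192	4374566	+	none	C-X10-C-X14-CC-X16-CXC-X21-C-X13-C	20	104	11873.64	7.04	Y	0
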