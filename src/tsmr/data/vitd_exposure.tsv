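snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pvalue	gene
rs6698680	1	2329661	G	A	0.464	-0.012	0.002	8.99E-10	RER1
rs3750296	1	17559656	C	G	0.341	-0.021	0.002	2.09E-24	PADI1
rs7519574	1	34726552	A	G	0.182	0.017	0.003	2.09E-11	RP4-657M3.2
rs56044892	1	41830086	T	C	0.211	0.015	0.002	2.85E-10	FOXO6
rs2934744	1	63048045	A	C	0.644	-0.022	0.002	3.96E-26	DOCK7
rs7528419	1	109817192	G	A	0.225	0.019	0.002	2.41E-16	CELSR2
rs3768013	1	150815411	A	G	0.370	-0.015	0.002	1.37E-13	ARNT
rs11264360	1	155284586	A	T	0.243	0.018	0.002	3.34E-15	FDPS
rs867772	1	220972343	G	A	0.682	-0.014	0.002	3.64E-11	MARC_1
rs10127775	1	230295789	T	A	0.605	0.012	0.002	3.43E-09	GALNT2
rs12997242	2	21381177	A	G	0.438	-0.013	0.002	2.23E-10	TDRD15
rs11127048	2	27752463	A	G	0.617	0.018	0.002	6.41E-19	GCKR
rs6724965	2	101440151	G	A	0.172	-0.017	0.003	1.29E-10	NPAS2
rs7569755	2	118648261	A	G	0.292	0.014	0.002	8.03E-11	HTR5BP
rs1047891	2	211540507	A	C	0.316	-0.014	0.002	1.16E-11	CPS1
rs2011425	2	234627608	G	T	0.079	-0.046	0.004	9.66E-38	UGT1A4
rs7650253	3	49431160	A	T	0.690	0.015	0.002	1.76E-10	RHOA
rs1972994	3	85631142	T	A	0.647	-0.018	0.002	7.99E-18	CADM2
rs6438900	3	125148287	G	C	0.261	0.014	0.002	9.59E-10	MRPL3
rs6773343	3	141825598	T	C	0.720	0.013	0.002	5.20E-09	TFDP2
rs78649910	4	3482213	A	T	0.110	-0.018	0.003	4.32E-09	DOK7
rs7699711	4	69947596	T	G	0.455	-0.029	0.002	6.97E-49	UGT2B7
rs145432346	4	72575017	C	T	0.826	0.109	0.003	6.78E-286	GC
rs705117	4	72608115	T	C	0.849	-0.034	0.003	1.71E-36	GC
rs11723621	4	72615362	G	A	0.291	-0.187	0.002	2.903E-1689	GC
rs200641845	4	72620895	T	A	0.545	0.018	0.002	6.92E-14	GC
rs3775150	4	72640750	C	T	0.262	-0.091	0.002	3.90E-295	GC
rs222026	4	72643760	T	A	0.871	-0.052	0.003	6.98E-68	GC
rs186881826	4	72785743	A	T	0.223	0.046	0.002	3.64E-77	GC
rs58073039	4	88287363	G	A	0.298	-0.014	0.002	2.16E-11	HSD17B11
rs7718395	5	118652574	G	C	0.320	0.013	0.002	1.67E-09	TNFAIP8
rs3822868	6	131934986	G	A	0.835	0.022	0.003	1.41E-15	MED23
rs111529171	7	21571932	C	G	0.216	-0.015	0.002	6.24E-11	DNAH11
rs1011468	7	104613791	A	G	0.476	-0.014	0.002	1.35E-12	LINC01004
rs1858889	7	107117447	C	A	0.501	0.013	0.002	3.85E-11	COG5
rs804280	8	11612698	A	C	0.582	0.013	0.002	4.43E-11	GATA4
rs34726834	8	25889606	T	C	0.254	0.014	0.002	6.65E-10	EBF2
rs7828742	8	116960729	G	A	0.597	-0.022	0.002	3.06E-28	LINC00536
rs10818769	9	125719923	G	C	0.857	-0.017	0.003	3.35E-09	DNAH11
rs532436	9	136149830	A	G	0.184	-0.015	0.003	2.17E-09	ABO
rs10887718	10	82042624	T	C	0.527	-0.012	0.002	1.44E-10	MAT1A
rs10832218	11	14181174	C	T	0.198	-0.034	0.003	7.09E-32	CYP2R1
rs10832289	11	14669496	T	A	0.410	-0.069	0.002	2.03E-266	CYP2R1
rs201501563	11	14882470	T	C	0.122	-0.066	0.004	9.17E-67	CYP2R1
rs523583	11	66070146	C	A	0.469	0.012	0.002	5.58E-10	TMEM151A
rs12803256	11	71132868	G	A	0.771	0.100	0.002	8.599E-407	FLJ42102
rs200454003	11	71228990	T	C	0.265	-0.087	0.003	3.68E-256	FLJ42102
rs10793129	11	75459865	A	G	0.090	0.024	0.003	1.64E-12	RP11-21L23.4
rs1149605	11	76485216	C	T	0.171	0.019	0.003	7.34E-14	RP11-21L23.4
rs964184	11	116648917	C	G	0.864	0.040	0.003	5.11E-44	ZPR1
rs2847500	11	120114421	A	G	0.124	-0.021	0.003	7.79E-13	ZPR1
rs12317268	12	21352541	G	A	0.152	-0.019	0.003	9.15E-12	SLCO1B1
rs9668081	12	38602911	T	C	0.471	0.012	0.002	5.38E-09	FAM166AP9
rs10859995	12	96375682	C	T	0.581	-0.039	0.002	7.03E-89	HAL
rs8018720	14	39556185	C	G	0.820	-0.032	0.003	4.04E-36	SEC23A
rs261291	15	58680178	C	T	0.356	-0.022	0.002	2.89E-28	LIPC
rs1800588	15	58723675	T	C	0.215	-0.030	0.002	2.65E-36	LIPC
rs17765311	15	63789952	C	A	0.345	-0.015	0.002	1.35E-13	AC007950.2
rs62007299	15	77711719	A	G	0.709	-0.014	0.002	1.69E-11	PEAK1
rs8063706	16	11909552	T	A	0.273	0.013	0.002	3.64E-09	BCAR4
rs77924615	16	20392332	A	G	0.198	-0.016	0.002	1.46E-10	PDILT
rs71383766	16	30930233	T	C	0.420	0.013	0.002	1.15E-09	FBXL19
rs1800775	16	56995236	A	C	0.486	-0.017	0.002	1.56E-17	CETP
rs2909218	17	66464546	T	C	0.793	0.017	0.002	2.81E-12	RP11-120M18.2
rs8091117	18	28919794	A	C	0.065	-0.024	0.004	1.03E-09	DSG1
rs2037511	18	61366207	A	G	0.165	0.016	0.003	9.29E-10	SERPINB11
rs57631352	19	4338173	G	A	0.297	-0.013	0.002	1.48E-09	STAP2
rs73015021	19	11192915	G	A	0.121	0.023	0.003	1.15E-14	LDLR
rs10500209	19	11979164	C	T	0.282	-0.013	0.002	6.18E-10	LDLR
rs58542926	19	19379549	T	C	0.076	0.032	0.004	8.57E-19	TM6SF2
rs3814995	19	36342212	T	C	0.312	-0.015	0.002	2.83E-12	NPHS1
rs1065853	19	45413233	T	G	0.082	0.027	0.004	8.32E-14	APOC1
rs157595	19	45425460	G	A	0.614	-0.016	0.002	2.95E-14	APOC1
rs112285002	19	48374320	T	C	0.160	0.060	0.003	1.77E-110	SULT2A1
rs62130059	19	48461240	C	A	0.336	-0.027	0.002	9.25E-34	SULT2A1
rs10426	19	51517798	A	G	0.213	0.025	0.002	3.31E-26	KLK10
rs8103262	19	53065814	C	T	0.305	0.013	0.002	3.18E-09	ZNF808
rs6123359	20	52714706	G	A	0.105	0.032	0.003	7.74E-24	RP13-379L11.3
rs6127099	20	52731402	T	A	0.279	-0.037	0.002	9.30E-62	RP13-379L11.3
rs2585442	20	52737123	G	C	0.246	0.034	0.002	6.87E-49	RP13-379L11.3
rs2229742	21	16339172	C	G	0.104	-0.026	0.003	7.13E-16	NRIP1
rs2074735	22	31535872	C	G	0.064	0.027	0.004	6.55E-12	PLA2G3
rs960596	22	41393520	T	C	0.340	0.012	0.002	2.23E-09	SCUBE1
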