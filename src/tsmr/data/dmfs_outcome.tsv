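snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pvalue	n
rs6698680	1	2329661	a	g	0.6092	-0.0017	0.0088	0.844	26790
rs3750296	1	17559656	c	g	0.3728	0.0133	0.0093	0.1507	26789
rs7519574	1	34726552	a	g	0.1836	0.0096	0.0127	0.4483	26791
rs56044892	1	41830086	t	c	0.22	0.0072	0.0129	0.5796	26789
rs2934744	1	63048045	a	c	0.733	-0.0067	0.0091	0.4594	26791
rs7528419	1	109817192	a	g	0.7889	0.0078	0.0106	0.4625	26790
rs3768013	1	150815411	a	g	0.426	-0.0074	0.009	0.4108	26790
rs11264360	1	155284586	a	t	0.3044	-0.0103	0.0102	0.3107	26791
rs867772	1	220972343	a	g	0.3268	0.0012	0.01	0.9073	26792
rs10127775	1	230295789	a	t	0.4673	-0.0008	0.0088	0.9285	26791
rs12997242	2	21381177	a	g	0.4487	0.0027	0.0089	0.7603	26791
rs11127048	2	27752463	a	g	0.6373	0.02	0.0092	0.02982	26790
rs6724965	2	101440151	a	g	0.8299	0.0292	0.0103	0.004574	26792
rs7569755	2	118648261	a	g	0.2943	-0.0006	0.0101	0.9555	26791
rs1047891	2	211540507	a	c	0.3562	0.0191	0.0095	0.04407	26791
rs2011425	2	234627608	t	g	0.937	-0.0044	0.015	0.7695	26791
rs7650253	3	49431160	a	t	0.4507	-0.0039	0.0098	0.6916	26789
rs1972994	3	85631142	a	t	0.3557	0.0018	0.0095	0.8508	26790
rs6438900	3	125148287	c	g	0.748	-0.0066	0.0097	0.5	26790
rs6773343	3	141825598	t	c	0.7932	0.0078	0.0101	0.44	26790
rs78649910	4	3482213	a	t	0.1488	-0.0307	0.0132	0.01993	26792
rs7699711	4	69947596	t	g	0.6559	-0.0022	0.0089	0.8041	26792
rs145432346	4	72575017	NA	NA	NA	NA	NA	NA	NA
rs705117	4	72608115	t	c	0.8864	-0.0063	0.0108	0.5627	26790
rs11723621	4	72615362	a	g	0.808	0.0015	0.0101	0.8812	26791
rs200641845	4	72620895	NA	NA	NA	NA	NA	NA	NA
rs3775150	4	72640750	NA	NA	NA	NA	NA	NA	NA
rs222026	4	72643760	a	t	0.2457	0.0242	0.0111	0.02888	26791
rs186881826	4	72785743	a	t	0.3269	0.0153	0.0098	0.1201	26790
rs58073039	4	88287363	a	g	0.7466	-0.0023	0.0095	0.8081	26791
rs7718395	5	118652574	c	g	0.79	0.0007	0.0099	0.9435	26791
rs3822868	6	131934986	g	a	0.22	0.0078	0.0111	0.48	26791
rs111529171	7	21571932	c	g	0.2175	-0.0058	0.0114	0.6131	26792
rs1011468	7	104613791	a	g	0.5819	0.0039	0.0089	0.6598	26791
rs1858889	7	107117447	a	c	0.5596	-0.0001	0.0087	0.9898	26791
rs804280	8	11612698	a	c	0.7116	-0.0033	0.0092	0.7233	26791
rs34726834	8	25889606	t	c	0.3408	0.0008	0.0095	0.934	26790
rs7828742	8	116960729	a	g	0.4595	0.0182	0.0092	0.04824	26790
rs10818769	9	125719923	c	g	0.4206	0.0054	0.0105	0.6048	26791
rs532436	9	136149830	a	g	0.2318	-0.0021	0.0113	0.8535	26791
rs10887718	10	82042624	t	c	0.6486	-0.002	0.0089	0.8233	26790
rs10832218	11	14181174	t	c	0.6556	0.0117	0.0089	0.1927	26791
rs10832289	11	14669496	a	t	0.628	0.0161	0.0088	0.06729	26791
rs201501563	11	14882470	t	c	0.6232	0.0175	0.0088	0.04597	26791
rs523583	11	66070146	a	c	0.5697	-0.0104	0.0088	0.2338	26791
rs12803256	11	71132868	a	g	0.5016	0.0161	0.009	0.07419	26792
rs200454003	11	71228990	t	c	0.4779	0.0127	0.0128	0.3216	12760
rs10793129	11	75459865	a	g	0.1507	0.0316	0.0146	0.03075	26790
rs1149605	11	76485216	t	c	0.8776	-0.0167	0.0124	0.1767	26792
rs964184	11	116648917	c	g	0.8952	-0.0167	0.011	0.1274	26789
rs2847500	11	120114421	a	g	0.2265	0.036	0.0121	0.002913	26791
rs12317268	12	21352541	a	g	0.8515	-0.015	0.0116	0.1983	26790
rs9668081	12	38602911	t	c	0.5563	-0.006	0.0087	0.4886	26791
rs10859995	12	96375682	t	c	0.5772	-0.0099	0.0088	0.2578	26791
rs8018720	14	39556185	c	g	0.8762	0.0229	0.0113	0.04263	26791
rs261291	15	58680178	t	c	0.6703	0.0022	0.009	0.8094	26790
rs1800588	15	58723675	t	c	0.4643	-0.007	0.0095	0.4646	26790
rs17765311	15	63789952	a	c	0.7866	-0.0167	0.0097	0.08395	26790
rs62007299	15	77711719	a	g	0.741	-0.004	0.0093	0.6685	26790
rs8063706	16	11909552	a	t	0.7396	0.0002	0.01	0.9868	26790
rs77924615	16	20392332	a	g	0.2262	0.0069	0.011	0.5283	26789
rs71383766	16	30930233	t	c	0.4351	-0.0071	0.0093	0.4419	26790
rs1800775	16	56995236	a	c	0.5197	0.0033	0.0087	0.708	26789
rs2909218	17	66464546	t	c	0.8359	-0.0022	0.0101	0.8276	26791
rs8091117	18	28919794	a	c	0.149	0.0106	0.014	0.4469	26791
rs2037511	18	61366207	a	g	0.1939	0.0054	0.0117	0.6434	26790
rs57631352	19	4338173	a	g	0.7205	-0.0121	0.0095	0.2048	26790
rs73015021	19	11192915	a	g	0.9088	0.0293	0.013	0.02379	26792
rs10500209	19	11979164	t	c	0.8095	0.0098	0.0102	0.336	26791
rs58542926	19	19379549	t	c	0.109	0.0062	0.017	0.7127	26791
rs3814995	19	36342212	t	c	0.3704	0.0069	0.0099	0.4851	26791
rs1065853	19	45413233	t	g	0.0786	0.1254	0.0795	0.1146	1116
rs157595	19	45425460	a	g	0.5123	-0.0003	0.0095	0.9767	26791
rs112285002	19	48374320	t	c	0.1274	0.0092	0.0185	0.6194	26791
rs62130059	19	48461240	a	c	0.6457	0.0115	0.0103	0.2643	26791
rs10426	19	51517798	a	g	0.2535	-0.0141	0.0114	0.2175	26790
rs8103262	19	53065814	t	c	0.7214	0.0115	0.0093	0.2167	26790
rs6123359	20	52714706	a	g	0.9227	-0.0161	0.014	0.2512	26789
rs6127099	20	52731402	a	t	0.764	-0.0011	0.0095	0.9087	26789
rs2585442	20	52737123	c	g	0.8644	-0.0103	0.0111	0.3531	26790
rs2229742	21	16339172	c	g	0.1364	-0.0044	0.0162	0.7857	26789
rs2074735	22	31535872	c	g	0.1578	0.0213	0.0149	0.1512	26789
rs960596	22	41393520	t	c	0.3741	-0.0014	0.0099	0.885	26789
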