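snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pvalue	n
rs6698680	1	2329661	a	g	0.5344	-0.0036	0.0306	0.907	13383
rs3750296	1	17559656	c	g	0.3503	-0.0269	0.0312	0.3879	13384
rs7519574	1	34726552	a	g	0.1671	-0.0232	0.0447	0.6033	7999
rs56044892	1	41830086	t	c	0.213	0.0012	0.0379	0.9742	13347
rs2934744	1	63048045	a	c	0.6568	-0.0361	0.0323	0.2644	12938
rs7528419	1	109817192	a	g	0.7784	0.029	0.0369	0.4311	12937
rs3768013	1	150815411	a	g	0.3645	0.06	0.0315	0.05649	13382
rs11264360	1	155284586	a	t	0.2454	0.0359	0.0356	0.3139	13383
rs867772	1	220972343	a	g	0.3112	-0.0437	0.0328	0.183	13359
rs10127775	1	230295789	a	t	0.4003	0.0494	0.0311	0.112	12927
rs12997242	2	21381177	a	g	0.4346	-0.0295	0.0309	0.3392	12938
rs11127048	2	27752463	a	g	0.5503	-0.0883	0.0735	0.2298	2070
rs6724965	2	101440151	a	g	0.8248	0.0626	0.0394	0.112	13381
rs7569755	2	118648261	a	g	0.285	0.0478	0.0331	0.1491	13384
rs1047891	2	211540507	a	c	0.3208	0.0051	0.0343	0.8819	12724
rs2011425	2	234627608	t	g	0.9169	-0.0554	0.0556	0.3198	13386
rs7650253	3	49431160	a	t	0.313	0.0048	0.0325	0.8835	13386
rs1972994	3	85631142	a	t	0.3446	0.0209	0.0313	0.5048	13385
rs6438900	3	125148287	c	g	0.7282	-0.0246	0.0339	0.4681	13385
rs6773343	3	141825598	t	c	0.7247	0.0046	0.0334	0.8901	13386
rs78649910	4	3482213	a	t	0.1162	-0.0106	0.0489	0.8289	13373
rs7699711	4	69947596	t	g	0.5042	0.0991	0.0688	0.1495	2075
rs145432346	4	72575017	NA	NA	NA	NA	NA	NA	NA
rs705117	4	72608115	t	c	0.8473	-0.0646	0.0454	0.1542	7999
rs11723621	4	72615362	a	g	0.7192	0.0019	0.0334	0.9556	13384
rs200641845	4	72620895	NA	NA	NA	NA	NA	NA	NA
rs3775150	4	72640750	NA	NA	NA	NA	NA	NA	NA
rs222026	4	72643760	a	t	0.1682	0.0295	0.0966	0.7598	2075
rs186881826	4	72785743	a	t	0.2567	0.0164	0.0885	0.8527	2064
rs58073039	4	88287363	a	g	0.7143	0.0342	0.0332	0.3042	13386
rs7718395	5	118652574	c	g	0.6673	0.0323	0.0318	0.3109	13378
rs3822868	6	131934986	g	a	0.1677	-0.0472	0.0396	0.2341	13386
rs111529171	7	21571932	c	g	0.2061	0.0092	0.0373	0.805	13380
rs1011468	7	104613791	a	g	0.4684	0.0249	0.0302	0.4102	13382
rs1858889	7	107117447	a	c	0.5063	0.0303	0.0302	0.3145	13383
rs804280	8	11612698	a	c	0.587	0.0001	0.0332	0.9966	7999
rs34726834	8	25889606	t	c	0.2557	0.0389	0.0346	0.2606	13385
rs7828742	8	116960729	a	g	0.3983	-0.0058	0.0306	0.8495	13383
rs10818769	9	125719923	c	g	0.1419	-0.0203	0.0431	0.6374	13386
rs532436	9	136149830	a	g	0.2028	-0.0193	0.0382	0.613	12938
rs10887718	10	82042624	t	c	0.5247	-0.0317	0.0299	0.2902	13386
rs10832218	11	14181174	t	c	0.74	-0.0027	0.0435	0.9509	13386
rs10832289	11	14669496	a	t	0.5874	0.0193	0.0305	0.5266	13386
rs201501563	11	14882470	t	c	0.5812	0.0325	0.0305	0.2856	13386
rs523583	11	66070146	a	c	0.5257	-0.0254	0.0332	0.4453	7999
rs12803256	11	71132868	a	g	0.2741	0.0204	0.0343	0.5516	13378
rs200454003	11	71228990	t	c	NA	NA	NA	NA	NA
rs10793129	11	75459865	a	g	0.0949	0.0029	0.1207	0.981	2079
rs1149605	11	76485216	t	c	0.8273	-0.1035	0.04	0.009713	13386
rs964184	11	116648917	c	g	0.8602	0.052	0.0489	0.2876	7551
rs2847500	11	120114421	a	g	0.1232	0.0182	0.0481	0.7058	13351
rs12317268	12	21352541	a	g	0.8355	-0.0478	0.045	0.2884	7999
rs9668081	12	38602911	t	c	0.4758	0.0012	0.069	0.9865	2071
rs10859995	12	96375682	t	c	0.4228	-0.0052	0.0333	0.8761	7999
rs8018720	14	39556185	c	g	0.8273	-0.0808	0.0413	0.0503	12937
rs261291	15	58680178	t	c	0.6439	0.0217	0.0315	0.4915	13379
rs1800588	15	58723675	t	c	0.2113	0.0153	0.0381	0.687	12938
rs17765311	15	63789952	a	c	0.6493	0.012	0.0324	0.7107	12924
rs62007299	15	77711719	a	g	0.7134	0.0339	0.033	0.3052	13385
rs8063706	16	11909552	a	t	0.7204	0.0659	0.0339	0.05223	13350
rs77924615	16	20392332	a	g	0.2008	-0.0209	0.0383	0.5846	13361
rs71383766	16	30930233	t	c	0.4139	-0.0694	0.0786	0.377	1865
rs1800775	16	56995236	a	c	0.4855	-0.0543	0.0339	0.1088	7550
rs2909218	17	66464546	t	c	0.7992	0.0058	0.0378	0.8787	13384
rs8091117	18	28919794	a	c	0.0674	0.1266	0.0678	0.06196	7551
rs2037511	18	61366207	a	g	0.1623	0.032	0.0459	0.4863	7551
rs57631352	19	4338173	a	g	0.7062	-0.0158	0.0332	0.6337	13383
rs73015021	19	11192915	a	g	0.8803	0.0302	0.0471	0.5211	13386
rs10500209	19	11979164	t	c	0.7215	-0.056	0.0373	0.1337	7551
rs58542926	19	19379549	t	c	0.0816	-0.1306	0.0566	0.02103	12938
rs3814995	19	36342212	t	c	0.3164	-0.0195	0.0375	0.6037	12724
rs1065853	19	45413233	t	g	0.0693	-0.2843	0.5623	0.6131	202
rs157595	19	45425460	a	g	0.3711	-0.0409	0.0332	0.2176	13172
rs112285002	19	48374320	t	c	0.12	-0.0908	0.119	0.4452	2051
rs62130059	19	48461240	a	c	0.4537	-0.0174	0.09	0.8464	1865
rs10426	19	51517798	a	g	0.2207	0.0615	0.0405	0.1292	7999
rs8103262	19	53065814	t	c	0.6963	0.0025	0.033	0.9406	13386
rs6123359	20	52714706	a	g	0.8982	-0.0575	0.0504	0.2544	13383
rs6127099	20	52731402	a	t	0.7268	-0.003	0.0347	0.9303	13172
rs2585442	20	52737123	c	g	0.7475	-0.0027	0.0351	0.9393	13366
rs2229742	21	16339172	c	g	0.1103	0.0045	0.0492	0.9277	12937
rs2074735	22	31535872	c	g	0.0704	0.0704	0.0631	0.2646	12935
rs960596	22	41393520	t	c	0.3344	0.0055	0.0319	0.8641	13373
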