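snp	chr	pos	effect_allele	other_allele	eaf	beta	se	pvalue	n
rs6698680	1	2329661	a	g	0.5311	0.0085	0.0297	0.775	17022
rs3750296	1	17559656	c	g	0.3472	-0.0313	0.0305	0.3044	17032
rs7519574	1	34726552	a	g	0.1692	-0.0617	0.0486	0.204	11767
rs56044892	1	41830086	t	c	0.2118	0.021	0.0375	0.5761	16926
rs2934744	1	63048045	a	c	0.6596	-0.0007	0.0314	0.9824	16588
rs7528419	1	109817192	a	g	0.7715	-0.0398	0.0356	0.2641	16586
rs3768013	1	150815411	a	g	0.3611	0.029	0.0306	0.3439	17029
rs11264360	1	155284586	a	t	0.2455	0.0043	0.0345	0.8997	17023
rs867772	1	220972343	a	g	0.3059	-0.0212	0.0325	0.5129	16945
rs10127775	1	230295789	a	t	0.4057	0.0107	0.0308	0.7277	16520
rs12997242	2	21381177	a	g	0.4302	-0.0229	0.03	0.4461	16588
rs11127048	2	27752463	a	g	0.5689	-0.0464	0.0565	0.412	4674
rs6724965	2	101440151	a	g	0.8233	-0.0312	0.0384	0.4174	17014
rs7569755	2	118648261	a	g	0.2819	0.0107	0.0322	0.7387	17032
rs1047891	2	211540507	a	c	0.318	-0.0028	0.0346	0.9356	15895
rs2011425	2	234627608	t	g	0.9174	-0.0563	0.0539	0.2958	17034
rs7650253	3	49431160	a	t	0.3065	-0.015	0.0317	0.6364	17037
rs1972994	3	85631142	a	t	0.3415	-0.0381	0.0307	0.2146	17037
rs6438900	3	125148287	c	g	0.7287	0.0337	0.0329	0.3066	17017
rs6773343	3	141825598	t	c	0.7199	-0.0373	0.0323	0.2479	17037
rs78649910	4	3482213	a	t	0.1197	0.0614	0.0471	0.1922	16995
rs7699711	4	69947596	t	g	0.493	0.0244	0.0521	0.6389	4705
rs145432346	4	72575017	NA	NA	NA	NA	NA	NA	NA
rs705117	4	72608115	t	c	0.8452	-0.0204	0.0491	0.6783	11766
rs11723621	4	72615362	a	g	0.7242	-0.0029	0.0329	0.9299	17031
rs200641845	4	72620895	NA	NA	NA	NA	NA	NA	NA
rs3775150	4	72640750	NA	NA	NA	NA	NA	NA	NA
rs222026	4	72643760	a	t	0.1671	0.0826	0.0721	0.2519	4698
rs186881826	4	72785743	a	t	0.2482	-0.0156	0.0656	0.8127	4652
rs58073039	4	88287363	a	g	0.7207	-0.0093	0.0322	0.7727	17030
rs7718395	5	118652574	c	g	0.6602	-0.0176	0.0308	0.5671	17005
rs3822868	6	131934986	g	a	0.1676	0.0219	0.0393	0.5771	17037
rs111529171	7	21571932	c	g	0.2021	-0.0843	0.0366	0.02117	17022
rs1011468	7	104613791	a	g	0.4725	0.0136	0.0292	0.6421	17023
rs1858889	7	107117447	a	c	0.5068	0.0076	0.0292	0.7947	17034
rs804280	8	11612698	a	c	0.5946	-0.0094	0.0358	0.7938	11767
rs34726834	8	25889606	t	c	0.258	0.0278	0.0337	0.4096	17037
rs7828742	8	116960729	a	g	0.3991	0.0619	0.0297	0.03707	17032
rs10818769	9	125719923	c	g	0.1417	0.0636	0.0427	0.1364	17037
rs532436	9	136149830	a	g	0.2008	0.0213	0.0373	0.5678	16586
rs10887718	10	82042624	t	c	0.5215	-0.0332	0.0291	0.2543	17037
rs10832218	11	14181174	t	c	0.6948	-0.0223	0.0388	0.566	17037
rs10832289	11	14669496	a	t	0.5866	0.0332	0.0298	0.2653	17037
rs201501563	11	14882470	t	c	0.5809	0.0359	0.0296	0.2263	17037
rs523583	11	66070146	a	c	0.529	-0.0026	0.0358	0.9424	11767
rs12803256	11	71132868	a	g	0.2959	0.0167	0.0325	0.6076	17018
rs200454003	11	71228990	t	c	NA	NA	NA	NA	NA
rs10793129	11	75459865	a	g	0.1022	0.0191	0.0875	0.8272	4707
rs1149605	11	76485216	t	c	0.8303	-0.0663	0.0392	0.09072	17037
rs964184	11	116648917	c	g	0.8614	0.1134	0.0538	0.03506	11318
rs2847500	11	120114421	a	g	0.1255	-0.0796	0.0462	0.0845	16952
rs12317268	12	21352541	a	g	0.8293	0.0422	0.0482	0.3808	11767
rs9668081	12	38602911	t	c	0.4807	-0.0715	0.0527	0.1749	4679
rs10859995	12	96375682	t	c	0.4209	0.0549	0.0357	0.1244	11767
rs8018720	14	39556185	c	g	0.8336	-0.0313	0.0404	0.4384	16585
rs261291	15	58680178	t	c	0.6454	-0.0072	0.0305	0.8145	17027
rs1800588	15	58723675	t	c	0.2144	-0.0273	0.0367	0.4563	16582
rs17765311	15	63789952	a	c	0.646	-0.0421	0.0314	0.1797	16556
rs62007299	15	77711719	a	g	0.7111	0.0149	0.0321	0.6416	17035
rs8063706	16	11909552	a	t	0.7121	0.0664	0.0342	0.05258	16344
rs77924615	16	20392332	a	g	0.2002	0.0277	0.0377	0.4623	16966
rs71383766	16	30930233	t	c	0.3967	-0.0534	0.0611	0.3818	4579
rs1800775	16	56995236	a	c	0.4822	-0.0302	0.0369	0.412	11318
rs2909218	17	66464546	t	c	0.7987	0.0284	0.0365	0.4361	17025
rs8091117	18	28919794	a	c	0.0721	0.1079	0.0716	0.1317	11318
rs2037511	18	61366207	a	g	0.1653	0.0182	0.0494	0.7126	11318
rs57631352	19	4338173	a	g	0.7039	-0.0281	0.0318	0.3775	17032
rs73015021	19	11192915	a	g	0.8841	0.0861	0.0466	0.06437	17024
rs10500209	19	11979164	t	c	0.7193	-0.0767	0.0403	0.05718	11317
rs58542926	19	19379549	t	c	0.0813	0.0191	0.056	0.7332	16584
rs3814995	19	36342212	t	c	0.3177	-0.0489	0.0403	0.2248	13471
rs1065853	19	45413233	t	g	0.0745	0.0724	0.2229	0.7453	644
rs157595	19	45425460	a	g	0.3653	-0.0109	0.0338	0.747	15328
rs112285002	19	48374320	t	c	0.1073	-0.2394	0.0987	0.01527	4608
rs62130059	19	48461240	a	c	0.4583	-0.0481	0.0969	0.6197	1591
rs10426	19	51517798	a	g	0.2184	0.0879	0.0438	0.04488	11766
rs8103262	19	53065814	t	c	0.6948	-0.0274	0.0317	0.388	17030
rs6123359	20	52714706	a	g	0.901	-0.1575	0.0511	0.002053	17024
rs6127099	20	52731402	a	t	0.7272	0.0092	0.035	0.7932	16344
rs2585442	20	52737123	c	g	0.7451	-0.0194	0.0343	0.5715	16990
rs2229742	21	16339172	c	g	0.1176	0.0698	0.047	0.1376	16579
rs2074735	22	31535872	c	g	0.0689	0.0605	0.0613	0.3235	16586
rs960596	22	41393520	t	c	0.3349	-0.0088	0.0313	0.7779	16993
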