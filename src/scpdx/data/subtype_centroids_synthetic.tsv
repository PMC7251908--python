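gene	luminal_papillary	luminal_infiltrated	luminal	basal_squamous	neuronal
SIG000	8.3441	5.5887	5.0945	5.1349	4.6473
SIG001	7.8808	4.9352	4.7472	4.7269	4.1745
SIG002	7.4247	4.1806	4.0292	4.3384	4.686
SIG003	8.908	5.8639	6.157	5.9179	6.0661
SIG004	7.0183	3.9001	3.296	3.6945	3.9677
SIG005	8.6908	5.6081	5.4641	6.0277	5.6319
SIG006	8.8847	5.6469	5.7795	5.7115	5.9173
SIG007	7.3394	4.3757	4.4983	4.2874	4.6687
SIG008	5.9305	2.2362	2.4586	3.5261	2.3365
SIG009	10.4076	7.7352	7.717	7.6572	7.594
SIG010	7.6456	4.5163	4.7649	4.5798	5.0203
SIG011	7.9541	4.5414	4.1513	4.1342	4.8233
SIG012	9.5396	6.7439	6.4095	6.3173	6.6688
SIG013	8.8247	6.0934	5.1504	6.1711	5.6809
SIG014	6.5975	2.9202	2.8009	2.7176	3.2187
SIG015	8.2308	5.8589	5.6421	5.4723	5.3267
SIG016	8.5721	5.9149	5.869	5.4946	5.8248
SIG017	7.4821	5.2334	4.8817	4.8707	5.1216
SIG018	5.7459	2.9056	2.2999	2.8349	2.7841
SIG019	5.9836	2.9425	3.3538	2.894	3.0838
SIG020	8.5409	5.6109	5.5692	5.6674	6.1888
SIG021	7.9896	4.776	4.9207	4.8955	5.1982
SIG022	6.6221	4.0636	4.3014	4.4471	3.7713
SIG023	10.02	6.8707	7.0421	5.7776	6.1524
SIG024	8.2329	5.9406	5.3969	5.7022	5.6552
SIG025	8.1484	5.3607	4.9839	5.151	5.0763
SIG026	7.4741	4.2443	4.5074	4.405	4.2803
SIG027	9.2475	5.5246	5.8344	6.3013	6.1139
SIG028	8.5278	4.7812	5.2896	5.0982	5.8388
SIG029	9.0574	5.513	6.1063	5.7218	6.4329
SIG030	5.1218	7.4185	4.4265	4.4596	4.5282
SIG031	4.2387	6.6963	4.3096	4.2764	4.6112
SIG032	6.2816	9.5709	6.7597	5.6689	6.7369
SIG033	5.1668	8.3448	5.7632	5.3013	5.0142
SIG034	3.145	6.0759	3.0539	3.1291	3.3738
SIG035	4.1454	6.7561	3.6914	3.4361	3.6245
SIG036	4.5524	7.2478	4.0251	4.3414	4.0292
SIG037	4.065	7.023	3.6204	4.0855	4.0022
SIG038	4.5018	7.6153	4.4229	4.7447	4.584
SIG039	4.4244	7.7465	4.743	4.5436	4.4023
SIG040	6.1768	9.5893	6.7249	6.6918	6.5197
SIG041	5.8745	8.6488	5.8525	5.6342	5.9581
SIG042	5.6417	8.7981	5.9941	5.8548	5.8571
SIG043	6.7536	9.4146	7.1546	6.3782	5.9557
SIG044	6.0148	8.2268	5.8041	6.6843	5.9943
SIG045	4.0075	6.5365	4.1432	4.168	3.6714
SIG046	4.4804	7.5375	4.357	4.3253	4.6668
SIG047	6.9269	9.9196	7.1043	7.1224	7.3376
SIG048	5.1858	7.774	5.7435	4.9271	5.2639
SIG049	5.8655	8.8821	5.4603	5.0004	5.4086
SIG050	5.0677	7.6378	4.1872	5.0711	4.7322
SIG051	4.9887	7.9243	5.5584	5.2752	5.2473
SIG052	5.2907	8.7126	5.0863	4.9461	4.6836
SIG053	6.2358	9.2243	6.6021	6.2726	6.2137
SIG054	4.0086	6.9933	3.558	3.7095	3.4673
SIG055	5.2138	7.8843	4.5492	5.2662	5.5338
SIG056	5.5533	9.0218	5.2275	5.549	5.4856
SIG057	3.731	7.0592	3.7275	3.7877	3.9605
SIG058	5.3588	8.1724	5.0946	5.7354	5.3918
SIG059	4.7567	7.7003	5.2092	5.0621	4.9503
SIG060	2.6629	2.334	5.9317	2.8088	2.8098
SIG061	3.802	4.1397	7.1059	4.5596	3.7499
SIG062	4.9566	4.9079	8.1366	5.1248	5.0307
SIG063	4.9532	5.8467	7.6708	4.7973	5.3408
SIG064	4.6835	4.4793	8.0298	4.7255	4.7564
SIG065	5.5117	5.5957	9.129	5.5486	5.4251
SIG066	5.461	5.3874	8.2103	5.3691	5.0685
SIG067	4.9339	5.3104	8.058	4.511	5.1749
SIG068	5.2384	5.79	7.9212	5.9893	5.5158
SIG069	6.143	5.6717	8.9865	5.993	5.7763
SIG070	4.6614	5.5039	8.163	5.2388	5.2086
SIG071	4.2035	3.7007	6.9563	4.0791	3.9812
SIG072	4.6797	4.5969	7.3761	4.5186	4.5093
SIG073	5.4666	5.1652	8.9337	5.992	5.8793
SIG074	4.8583	5.3141	8.3006	5.5407	5.1627
SIG075	4.0651	3.9218	7.7297	4.3355	4.4199
SIG076	4.5297	4.3576	7.5618	4.4432	4.3645
SIG077	3.7455	4.175	6.814	4.0441	3.8662
SIG078	4.5026	4.1835	7.4908	4.3299	4.857
SIG079	5.1635	4.95	7.9073	5.1113	5.6875
SIG080	4.6137	5.1069	8.2664	5.0816	4.8237
SIG081	4.0996	3.9859	6.9397	3.6787	3.8202
SIG082	5.8168	5.7853	8.5378	5.6882	5.4396
SIG083	5.1068	5.5822	8.0836	4.8472	5.5988
SIG084	5.9147	5.9619	9.5639	5.7843	6.0662
SIG085	4.678	5.2547	7.6328	4.6509	4.7968
SIG086	3.5802	2.9995	5.9025	3.6579	3.3567
SIG087	4.5797	4.2326	7.6929	4.2526	4.8759
SIG088	4.6766	4.5118	7.8312	4.2458	4.4322
SIG089	6.7576	6.2515	8.6639	6.3285	6.5946
SIG090	4.2287	3.7772	3.8412	7.0867	3.4513
SIG091	5.2475	5.4596	5.2682	8.7849	5.6408
SIG092	4.3532	4.7896	4.5669	7.438	4.2627
SIG093	5.4267	5.1555	4.9859	8.4904	5.9169
SIG094	5.0584	5.1831	4.9916	8.2393	4.6205
SIG095	3.9041	3.7463	3.9145	7.4243	4.439
SIG096	6.5669	5.9473	6.6227	9.7948	6.6865
SIG097	5.4523	5.7781	5.2231	8.5139	6.1422
SIG098	4.9306	5.1246	4.9862	7.9452	5.0767
SIG099	5.422	5.0254	4.716	8.579	5.4905
SIG100	4.3398	5.3275	5.1452	7.7193	4.53
SIG101	4.9038	4.9969	5.0071	7.6384	4.7749
SIG102	5.3272	5.0151	5.304	8.909	5.5182
SIG103	3.2863	3.9598	3.2404	6.6317	4.1002
SIG104	5.1522	5.2317	5.3947	7.5609	4.8335
SIG105	4.1991	4.5734	4.5918	6.8886	4.7636
SIG106	4.4537	4.0521	5.2922	8.3479	5.0277
SIG107	5.3389	5.753	5.5841	8.5183	6.6777
SIG108	4.946	5.0043	4.7902	8.3546	4.4078
SIG109	4.5567	5.6203	5.3272	8.2087	5.2303
SIG110	5.0748	5.6384	5.2245	8.6441	5.5343
SIG111	4.2758	4.048	3.6784	6.9658	4.1909
SIG112	3.7905	4.2487	3.5755	6.8602	3.7724
SIG113	5.3535	5.5866	5.6565	8.4358	5.5855
SIG114	4.0709	4.4037	4.2719	7.5007	4.0507
SIG115	4.5381	4.782	5.0853	7.9748	5.1705
SIG116	4.0089	3.7861	4.0648	6.7293	4.5538
SIG117	4.035	3.8388	4.1952	7.1303	4.5013
SIG118	6.1544	5.9495	5.7712	9.4831	5.6409
SIG119	5.7018	6.06	6.1989	8.5272	5.8354
SIG120	7.0286	7.2551	6.9112	7.5467	10.0076
SIG121	2.2745	1.756	1.9531	2.0481	5.1518
SIG122	4.3688	4.8177	5.1667	4.7257	7.9216
SIG123	5.5951	6.0368	5.8935	5.3119	8.6065
SIG124	3.9159	3.0237	3.2471	3.2785	6.9244
SIG125	4.8696	4.8567	4.0508	4.2121	7.7018
SIG126	5.0653	5.3242	5.5065	5.111	8.6789
SIG127	6.3733	5.9061	5.7312	5.4871	8.6487
SIG128	6.9957	7.5554	7.0489	7.2031	9.6527
SIG129	4.8228	4.9123	4.6034	5.1203	7.6979
SIG130	5.3965	5.9799	5.5024	4.9958	9.378
SIG131	4.4714	4.5904	4.9804	5.0265	7.282
SIG132	3.8843	3.5769	3.6589	3.4255	6.5618
SIG133	4.3911	4.8888	4.7382	5.0828	8.0168
SIG134	4.7013	5.0437	5.081	4.6281	7.7339
SIG135	5.084	4.948	5.0219	5.2367	8.3802
SIG136	5.8224	6.0364	5.8477	5.6162	8.6451
SIG137	4.5522	4.61	4.5934	4.8752	7.8769
SIG138	4.4842	4.9376	4.9745	5.4212	8.0486
SIG139	6.5301	6.0078	6.2779	6.1135	8.6447
SIG140	4.2216	4.6396	4.6837	4.2837	7.0487
SIG141	6.4913	5.552	5.9127	5.6928	8.8549
SIG142	6.088	6.4621	6.4582	6.3343	9.3788
SIG143	3.2362	3.7173	3.2181	4.2582	6.7292
SIG144	3.4956	3.4553	3.964	3.4982	6.8409
SIG145	5.6249	5.8632	5.5579	5.8365	8.8786
SIG146	4.5316	4.3212	4.5981	4.0463	7.5745
SIG147	4.5357	4.8183	4.6774	4.5714	7.9511
SIG148	5.4083	4.9177	4.5297	4.2683	7.6673
SIG149	4.4494	5.314	4.9518	5.0022	8.4737
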