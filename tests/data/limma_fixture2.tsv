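	A_1	A_2	A_3	B_1	B_2	B_3
Q00	26.475341	28.169175	23.232529	19.80587	24.515424	24.088228
Q01	25.830807	26.60491	24.157266	19.879546	23.546286	21.354545
Q02	22.564928	27.710778	26.35299	24.973372	21.63128	22.424376
Q03	25.59281	25.694877	26.677442	23.289013	24.323329	24.308519
Q04	28.748838	24.953379	27.48597	23.900628	23.984421	22.39
Q05	25.276531	28.47586	26.280723	24.215491	23.227102	27.069533
Q06	23.993253	23.308593	23.78254	23.381372	22.978345	23.833429
Q07	27.356993	24.118616	21.048331	21.63196	26.846112	24.396796
Q08	24.117698	23.868907	24.094161	25.974925	25.354943	24.528927
Q09	22.369554	24.79908	22.930231	25.710145	22.012808	23.78484
Q10	23.991772	22.518798	25.925487	25.633009	23.481626	24.862929
Q11	24.398272	21.251191	24.263356	23.935481	24.087524	22.867398
Q12	23.733845	23.823854	25.174013	24.330463	23.994511	25.510848
Q13	23.166181	23.41519	21.271768	26.356336	25.448144	25.376836
Q14	25.111897	24.183098	24.358203	23.581094	23.661559	24.090268
Q15	26.712892	24.99715	23.895097	22.960314	22.860532	26.875963
Q16	25.513906	24.201831	22.96566	20.686314	23.800228	26.61036
Q17	23.042136	23.445486	23.460635	24.267431	20.112755	23.425584
Q18	22.308396	25.751376	22.474304	25.142486	27.018209	23.379116
Q19	22.213203	24.568591	23.993973	21.048768	25.369019	29.98647
Q20	23.772517	23.821198	23.079066	24.281223	22.900998	23.024425
Q21	24.937449	23.33669	24.792173	25.116703	24.189975	24.405399
Q22	27.814419	23.615621	22.841352	21.35598	24.08149	26.890036
Q23	24.401728	23.6056	23.641903	23.788932	24.122356	23.914048
Q24	24.084996	24.117609	23.881585	23.984078	24.08188	23.96672
Q25	24.851051	27.162154	25.000551	24.094331	21.150123	24.655725
Q26	20.965603	21.803659	25.332174	25.100848	23.766282	21.334509
Q27	22.969005	22.115583	25.768095	30.268257	24.602276	21.836357
Q28	21.660172	23.887873	23.646606	21.698216	24.232584	21.699426
Q29	25.877368	25.793879	25.831188	23.199747	24.868571	23.777051
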