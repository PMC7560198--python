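	A_1	A_2	A_3	A_4	B_1	B_2	B_3	B_4
P00	26.484948	24.467896	27.153549	27.43872	22.073447	23.046731	25.191761	24.525636
P01	26.43411	25.179746	27.778409	27.626	25.099046	26.690862	25.701264	23.711061
P02	26.816771	24.825321	27.58132	26.188756	24.722706	23.978606	26.833812	24.768206
P03	26.712826	26.827117	28.153781	27.903483	25.619099	25.646232	28.212471	24.390377
P04	25.475301	25.023006	27.167634	27.937123	24.829079	23.739765	23.763278	25.975889
P05	26.114881	25.814731	24.001735	25.348242	25.175029	25.328033	26.307143	25.335393
P06	26.01837	25.101369	25.433679	25.946932	22.814266	24.520493	24.294441	24.041683
P07	24.587287	27.242412	23.701253	26.452418	22.475695	24.497672	25.24413	25.879333
P08	26.06684	26.190021	24.476912	24.306472	26.286964	24.713044	23.086471	23.300069
P09	23.620822	25.745741	25.213639	26.035728	24.359121	25.23781	25.938386	24.53598
P10	25.685163	24.007111	24.455419	24.427393	23.206241	25.730459	24.295896	25.018741
P11	25.72112	25.669797	25.998078	24.852272	24.365053	24.880423	22.468998	22.829331
P12	23.015951	23.50413	25.599661	23.641781	24.432756	26.948842	24.465604	26.106273
P13	23.599573	24.691844	23.574967	24.49145	26.260462	22.409019	25.651635	25.356603
P14	24.108775	22.830913	25.108194	24.205761	25.349014	25.032778	27.402668	24.640967
P15	23.464754	25.268913	25.329995	27.038781	26.252667	25.535307	27.194954	23.216855
P16	24.040373	23.610136	24.415285	22.934971	25.952726	24.666666	22.793791	23.476631
P17	25.470271	26.25719	27.995096	29.370794	25.621614	23.515693	21.801931	25.401567
P18	23.780588	24.376964	24.081855	24.788814	26.59897	25.235573	24.762048	23.446519
P19	22.487976	24.270538	24.919326	27.651895	25.195412	26.474109	24.251057	23.222584
P20	23.552325	23.912161	28.192705	23.76792	26.257734	23.645609	26.39736	25.577426
P21	24.765043	24.938856	24.017818	25.669108	24.317525	23.161591	23.083094	25.258882
P22	27.368637	25.239987	24.822043	25.428739	26.959003	25.329074	24.383609	26.659433
P23	25.643135	27.303634	25.274852	23.163296	22.947761	27.476392	27.585499	24.730721
P24	24.425219	27.192166	23.339431	23.657909	25.96499	24.408092	24.992317	24.754836
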