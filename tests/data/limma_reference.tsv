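t	p
P00	 2.9272262365194	0.003953061069473
P01	 1.5899865555309	0.113943281188639
P02	 1.3966538929610	0.164580751872175
P03	 1.5662014060893	0.119408688365529
P04	 1.9943212471812	0.047929207627354
P05	-0.2367494998254	0.813174137466423
P06	 1.8670393683257	0.063847755593698
P07	 1.0625021230167	0.289715386853402
P08	 0.9988475145913	0.319477156299045
P09	 0.1488917440101	0.881839040951648
P10	 0.0885064864441	0.929592184213871
P11	 2.1043318007381	0.037017206174140
P12	-1.6927555475095	0.092577971439002
P13	-0.9075900056789	0.365550645169595
P14	-1.6872420206149	0.093635247014007
P15	-0.2999907577617	0.764599530397093
P16	-0.5164281270700	0.606315929517800
P17	 3.4862904276988	0.000642630587046
P18	-0.8242102134957	0.411128770151122
P19	 0.0510053179943	0.959389141069997
P20	-0.6706059458537	0.503502810776086
P21	 0.9758934402072	0.330688487941828
P22	-0.1289568778282	0.897564519467060
P23	-0.3705544977424	0.711492131081791
P24	-0.4115762532286	0.681237526385016
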