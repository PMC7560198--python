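t	p
Q00	 1.7603175323788	0.13085033335138
Q01	 3.4026429469986	0.01537223191231
Q02	 1.5895029500065	0.16505153256879
Q03	 3.3856510185708	0.01568875667343
Q04	 3.2666855989663	0.01811767941685
Q05	 1.3992814472046	0.21316744644045
Q06	 0.5819308664154	0.58263490567920
Q07	-0.0580156872058	0.95569443224995
Q08	-2.2405099619569	0.06809902268208
Q09	-0.4034619790046	0.70114438970140
Q10	-0.4812985516093	0.64802482740346
Q11	-0.3219729227077	0.75882630316006
Q12	-0.5273471308022	0.61761827712788
Q13	-4.0947078399013	0.00696166699573
Q14	 1.5066616988118	0.18459214608293
Q15	 0.7091029589751	0.50590889497475
Q16	 0.3277872532098	0.75464755462535
Q17	 0.6219306368714	0.55776341285878
Q18	-1.2342142433299	0.26505395015866
Q19	-0.8260096929642	0.44163234085790
Q20	 0.2573192453268	0.80586897175795
Q21	-0.3299944460520	0.75306364163724
Q22	 0.3407172128764	0.74538786572119
Q23	-0.1190444565119	0.90927931537425
Q24	 0.0389306024949	0.97025862490950
Q25	 2.0064032050711	0.09354685741079
Q26	-0.4641232791436	0.65956559349943
Q27	-0.8470769168732	0.43070521557028
Q28	 0.5137215546690	0.62653246017116
Q29	 3.1587280870266	0.02068453318418
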