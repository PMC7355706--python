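time_min,compartment,mean_conc_ug_per_ml,sd,n
0.0,stomach,0.0,0.0,3
2.5,stomach,1.6569527403519444,0.038329376306735156,3
5.0,stomach,3.287831480445479,0.17165372462757347,3
7.5,stomach,4.500684314974929,0.1517097458091713,3
10.0,stomach,5.601192855322854,0.3148530670592939,3
12.5,stomach,7.023426775234182,0.07514495926203,3
15.0,stomach,8.540762812086207,0.24488078051664114,3
17.5,stomach,9.571323313358967,0.47775858186765113,3
20.0,stomach,10.412980744164047,0.42695991226266533,3
30.0,stomach,13.157406657417013,0.3852518556935321,3
40.0,stomach,14.97895048906816,0.3658061445585724,3
50.0,stomach,16.599982093920527,0.13332295892057824,3
60.0,stomach,16.48939714739102,0.5999088132536161,3
0.0,duodenum,0.0,0.0,3
2.5,duodenum,0.2582937743047428,0.006717596621493857,3
5.0,duodenum,0.8825005123769447,0.05012307584046266,3
7.5,duodenum,1.7050739931411816,0.059217824708059634,3
10.0,duodenum,2.4465669396582777,0.11674114292209373,3
12.5,duodenum,3.3217289847862,0.16439010687923297,3
15.0,duodenum,3.9648837824068646,0.19615789455831534,3
17.5,duodenum,4.564134751966237,0.34451489174784644,3
20.0,duodenum,4.915877010615335,0.1051217304556396,3
30.0,duodenum,6.24528452663213,0.14465850763408067,3
40.0,duodenum,6.084277342010576,0.47331541490015,3
50.0,duodenum,6.4437240521660755,0.3858992904121069,3
60.0,duodenum,5.8760536026278,0.3467947900996804,3
0.0,jejunum,0.0,0.0,3
2.5,jejunum,0.08271468550649107,0.0015495157474754273,3
5.0,jejunum,0.2984578424116737,0.01624953157845894,3
7.5,jejunum,0.6125713567673429,0.03874228188815297,3
10.0,jejunum,0.9424076131760528,0.051998918403235846,3
12.5,jejunum,1.3047517262932378,0.057242064811441784,3
15.0,jejunum,1.607550204314163,0.062203689899963666,3
17.5,jejunum,1.9939557362787454,0.12579465947871962,3
20.0,jejunum,2.2767318584411673,0.111602021090469,3
30.0,jejunum,3.121320705117599,0.155907403546723,3
40.0,jejunum,3.6085208258798076,0.2508536265981606,3
50.0,jejunum,4.12843747925725,0.02908041921732601,3
60.0,jejunum,4.41803329266914,0.23969930749377794,3
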