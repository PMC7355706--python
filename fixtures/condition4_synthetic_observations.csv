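time_min,compartment,mean_conc_ug_per_ml,sd,n
0.0,stomach,0.0,0.0,3
2.5,stomach,2.3394339367617736,0.05411683841256857,3
5.0,stomach,4.591014083629227,0.23969131993523746,3
7.5,stomach,6.217274099243315,0.2095728132017196,3
10.0,stomach,7.656772225502844,0.4304008594674656,3
12.5,stomach,9.503352732146782,0.10167815181444137,3
15.0,stomach,11.442040788176422,0.32806623255557493,3
17.5,stomach,12.699072553666758,0.6338821389312204,3
20.0,stomach,13.686115274225676,0.5611671355461848,3
30.0,stomach,16.69448082451962,0.48881819076867256,3
40.0,stomach,18.416591311393244,0.4497579632463788,3
50.0,stomach,19.84576678139204,0.1593915182783198,3
60.0,stomach,19.23043058109721,0.6996316896938458,3
0.0,duodenum,0.0,0.0,3
2.5,duodenum,0.36592502893459855,0.009516825346285422,3
5.0,duodenum,1.2404335616890505,0.07045247522874953,3
7.5,duodenum,2.3776860210422956,0.0825778790664061,3
10.0,duodenum,3.384834630789078,0.16151181355201014,3
12.5,duodenum,4.567938612382971,0.2260641732503483,3
15.0,duodenum,5.650372531269599,0.27954543942046023,3
17.5,duodenum,6.8722092685104705,0.5187354363692871,3
20.0,duodenum,7.8171790738565425,0.1671635376049718,3
30.0,duodenum,11.718791394462407,0.2714404551416359,3
40.0,duodenum,12.655518518116123,0.9845133056014216,3
50.0,duodenum,14.363910016412325,0.860220369153388,3
60.0,duodenum,13.729454407843162,0.8102892828312231,3
0.0,jejunum,0.0,0.0,3
2.5,jejunum,0.11740880979572776,0.002199449814223755,3
5.0,jejunum,0.4212451944413245,0.0229346866345927,3
7.5,jejunum,0.8597516556519555,0.054375283187988,3
10.0,jejunum,1.3154261560392226,0.07258084123794917,3
12.5,jejunum,1.8115670277894722,0.0794770645826993,3
15.0,jejunum,2.2359984251112914,0.08652131191869654,3
17.5,jejunum,2.813735096859173,0.17751289155159092,3
20.0,jejunum,3.2830113968750276,0.16092835254001206,3
30.0,jejunum,4.9558957594044175,0.24754291951805288,3
40.0,jejunum,6.198301686277246,0.4308874832038808,3
50.0,jejunum,7.533839181171314,0.05306782597657084,3
60.0,jejunum,8.448746414916046,0.4583846545942218,3
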