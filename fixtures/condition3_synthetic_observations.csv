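time_min,compartment,mean_conc_ug_per_ml,sd,n
0.0,stomach,0.0,0.0,3
2.5,stomach,4.588445627531189,0.10614198874693327,3
5.0,stomach,8.676003089043185,0.4529636795474707,3
7.5,stomach,11.331085969667718,0.3819499551391511,3
10.0,stomach,13.468648972275494,0.757096844832977,3
12.5,stomach,16.14537854514292,0.17274243070674888,3
15.0,stomach,18.784158111325496,0.538579445519783,3
17.5,stomach,20.152820253708683,1.0059406113266698,3
20.0,stomach,20.99958797667952,0.8610389724479407,3
30.0,stomach,22.35937146303228,0.6546874754698232,3
40.0,stomach,21.31717081362265,0.5205940211845205,3
50.0,stomach,19.46205408770849,0.1563097250927704,3
60.0,stomach,15.556785664010564,0.56597901926415,3
0.0,duodenum,0.0,0.0,3
2.5,duodenum,1.2685868537926446,0.03299287714559716,3
5.0,duodenum,3.774041028404319,0.21435290069375965,3
7.5,duodenum,6.493682389054649,0.22552789320094405,3
10.0,duodenum,8.437995408548751,0.4026299922547578,3
12.5,duodenum,10.525293995935323,0.520889636948669,3
15.0,duodenum,12.15066874345726,0.6011398388946593,3
17.5,duodenum,13.892427494349283,1.0486430428612288,3
20.0,duodenum,14.9364818797703,0.31940360158119907,3
30.0,duodenum,18.518843505385565,0.4289489539146443,3
40.0,duodenum,17.034322318344977,1.3251544731499723,3
50.0,duodenum,16.652904079777414,0.9973027733127011,3
60.0,duodenum,13.748965407425485,0.811440789175848,3
0.0,jejunum,0.0,0.0,3
2.5,jejunum,0.41773187214586,0.007825479963429327,3
5.0,jejunum,1.3398450093357355,0.0729478361617684,3
7.5,jejunum,2.4876868891399826,0.15733459562512417,3
10.0,jejunum,3.509304026251795,0.19363172703818632,3
12.5,jejunum,4.503006574191385,0.19755589432980072,3
15.0,jejunum,5.222250884509716,0.2020734865561746,3
17.5,jejunum,6.216974811109824,0.39221644448882037,3
20.0,jejunum,6.901210819880208,0.33828712529958466,3
30.0,jejunum,8.89200328122453,0.4441482548178031,3
40.0,jejunum,9.918072318502935,0.6894748651901383,3
50.0,jejunum,11.05540753704316,0.0778735023627973,3
60.0,jejunum,11.59030722296198,0.6288292620143855,3
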