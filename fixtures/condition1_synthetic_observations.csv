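time_min,compartment,mean_conc_ug_per_ml,sd,n
0.0,stomach,0.0,0.0,3
2.5,stomach,1.383210802342808,0.03199705463130905,3
5.0,stomach,2.75413650390842,0.14379015221442804,3
7.5,stomach,3.7804526581232953,0.12743206847438857,3
10.0,stomach,4.713987097534863,0.2649816448163057,3
12.5,stomach,5.917132792822638,0.06330851262414618,3
15.0,stomach,7.1958248921887344,0.20631871588409387,3
17.5,stomach,8.055592181234315,0.4020999156134456,3
20.0,stomach,8.744036746525774,0.3585287684518687,3
30.0,stomach,10.788978339391365,0.31590373654254944,3
40.0,stomach,11.644458138713636,0.28437335047640583,3
50.0,stomach,11.791574207062418,0.09470417225286555,3
60.0,stomach,10.272311064695764,0.3737219672199272,3
0.0,duodenum,0.0,0.0,3
2.5,duodenum,0.3763610428527125,0.009788240838303717,3
5.0,duodenum,1.163838247623753,0.06610211771385319,3
7.5,duodenum,2.0821927018482627,0.07231529125565755,3
10.0,duodenum,2.812267014554591,0.1341910005238048,3
12.5,duodenum,3.5157563542012578,0.17399238934770786,3
15.0,duodenum,3.7641424285607905,0.18622645558500756,3
17.5,duodenum,4.008309635410587,0.3025595069340194,3
20.0,duodenum,4.074206460138011,0.08712334185709096,3
30.0,duodenum,4.451854693968539,0.10311758471323858,3
40.0,duodenum,3.944493970192402,0.30685481530922465,3
50.0,duodenum,3.9463413763823447,0.2363369884466048,3
60.0,duodenum,3.5168734237522905,0.20755994810052356,3
0.0,jejunum,0.0,0.0,3
2.5,jejunum,0.1226899134455806,0.0022983821044136824,3
5.0,jejunum,0.40428716816365523,0.02201140721502482,3
7.5,jejunum,0.7706324721324517,0.048738910394171574,3
10.0,jejunum,1.1149899689990663,0.06152143892706208,3
12.5,jejunum,1.4614251408993983,0.06411564050587255,3
15.0,jejunum,1.691238802517652,0.06544199598635643,3
17.5,jejunum,1.9780298978926762,0.12478993034645319,3
20.0,jejunum,2.1472059773312373,0.10525285438390343,3
30.0,jejunum,2.5589233081393297,0.1278161158490002,3
40.0,jejunum,2.724287290276901,0.1893843432356011,3
50.0,jejunum,2.9642734950099343,0.020880131125348953,3
60.0,jejunum,3.079508473227109,0.16707797328702453,3
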