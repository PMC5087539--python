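no,unit,census_population,dwelling_objects,model_population
1,Anzhen Sub-district,48467,711,46031.227
2,Olympic Village Sub-district,57509,1771,55101.244
3,Changying Sub-district,24770,1240,32120.220
4,Chaowai Sub-district,43162,496,39569.780
5,Chaoyangbalizhuang Sub-district,85897,1049,61229.257
6,Cuigezhuang Sub-district,24448,4691,30771.512
7,Datun Sub-district,71615,2345,77291.336
8,Dongba Village,37907,4732,38612.750
9,Dongfeng Sub-district,30926,1187,37596.391
10,Dougezhuang Village,12719,2178,18841.690
11,Fatou Sub-district,31964,735,29591.992
12,Gaobeidian District,48234,2969,71468.861
13,Guanzhuang Sub-district,57269,2853,73120.667
14,Hepingjie Sub-district,98710,881,59449.281
15,Heizhuanghu Village,49681,3806,51199.561
16,Hujialou Sub-district,64264,416,49410.197
17,Jianwai Sub-district,42302,1265,54101.568
18,Jiangtai Sub-district,26119,2200,28267.330
19,Jianzhan Sub-district,59144,6891,60010.514
20,Jingsong Sub-district,73200,1003,59991.594
21,Jiuxianqiao Sub-district,69146,1297,70233.239
22,Laiguangying Sub-district,47269,3889,51471.291
23,Liulitun Sub-district,62168,891,48996.313
24,Maizidian Sub-district,21674,954,24664.127
25,Nanmofang Sub-district,59499,2014,70155.476
26,Panjiayuan Sub-district,81055,762,59981.261
27,Pingfang Sub-district,33492,2673,46781.497
28,Sanjianfang Sub-district,71011,1443,78501.201
29,Sanlitun Sub-district,38285,728,36799.497
30,Shibalidian Sub-district,38950,6658,41719.462
31,Beijing Airport Sub-district,24735,832,25184.881
32,Shuangjing Sub-district,72360,1063,66849.199
33,Sunhe Sub-district,21979,3760,26109.591
34,Taiyanggong Sub-district,45381,1147,48487.497
35,Tuanjiehu Sub-district,36869,264,33996.495
36,Wangsiying Village,19517,2394,27106.487
37,Wangjing Sub-district,82815,2321,82599.481
38,Xiangheyuan Sub-district,34636,350,32841.498
39,Xiaoguan Sub-district,51401,663,45998.869
40,Xiaohongmen Sub-district,29112,2100,40009.487
41,Yayuncun Sub-district,48858,858,53299.819
42,Zuojiazhuang Sub-district,67016,799,59996.794
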