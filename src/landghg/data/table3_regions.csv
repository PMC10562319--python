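code,region,area_km2,emission_tg,sink_tg,net_tg,intensity_gg_km2,per_capita_mg
1,Uusimaa,9569,16.973,-3.614,13.360,1.40,7.8
2,Southwest Finland,10914,6.989,-4.069,2.920,0.27,6.0
4,Satakunta,8269,5.787,-2.897,2.890,0.35,13.5
5,Kanta-Hame,5708,3.973,-1.740,2.232,0.39,13.1
6,Pirkanmaa,15550,8.827,-5.386,3.441,0.22,6.5
7,Paijat-Hame,6942,4.005,-2.231,1.774,0.26,8.6
8,Kymenlaakso,4948,3.633,-1.393,2.240,0.45,13.9
9,South Karelia,6872,4.531,-1.694,2.837,0.41,22.5
10,South Savo,17099,8.072,-4.102,3.969,0.23,30.1
11,North Savo,21078,9.542,-6.283,3.259,0.15,13.1
12,North Karelia,22903,7.902,-6.728,1.174,0.05,7.2
13,Central Finland,19012,8.732,-6.564,2.168,0.11,8.0
14,South Ostrobothnia,14356,7.247,-4.878,2.368,0.16,12.3
15,Ostrobothnia,7580,4.824,-2.939,1.885,0.25,10.7
16,Central Ostrobothnia,5224,2.550,-1.585,0.965,0.18,14.2
17,North Ostrobothnia,39194,18.660,-10.333,8.328,0.21,20.0
18,Kainuu,22688,5.537,-7.292,-1.754,-0.08,-24.6
19,Lapland,98982,19.372,-19.498,-0.126,-0.001,-0.7
0,Total,336887,147.157,-93.226,53.931,0.16,9.8
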