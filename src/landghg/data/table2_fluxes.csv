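category,source,kind,level,ch4_tg,co2_tg,n2o_tg,total_tg,sd_tg,intensity_gg_km2
artificial,industrial_processes,emission,component,0.00,8.51,0.00,8.51,0.30,1.07
artificial,energy_waste_solids,emission,component,0.00,6.49,0.00,6.49,0.13,0.81
artificial,energy_peat,emission,component,0.00,5.76,0.04,5.80,0.20,0.73
artificial,energy_gaseous,emission,component,0.00,5.72,0.00,5.72,1.59,0.72
artificial,energy_liquid,emission,component,0.00,1.67,0.00,1.67,0.07,0.21
artificial,energy_biomass,emission,component,0.01,0.00,0.09,0.10,0.05,0.01
artificial,energy_total,emission,subtotal,0.01,19.63,0.13,19.77,0.59,2.48
artificial,road_traffic,emission,component,0.00,10.37,0.00,10.37,0.31,1.30
artificial,machinery,emission,component,0.00,3.16,0.00,3.16,0.19,0.40
artificial,waste_management,emission,component,1.88,0.00,0.10,1.98,0.70,0.25
artificial,residential_combustion,emission,component,0.19,1.66,0.03,1.88,0.44,0.24
artificial,total,emission,category_total,2.08,43.34,0.26,45.68,1.97,5.73
arable,livestock_production,emission,component,2.80,0.00,0.24,3.04,2.28,1.53
arable,field_cultivation,emission,component,0.00,0.20,3.22,3.43,2.57,0.17
arable,organic_annual,emission,component,0.00,2.78,0.00,2.78,0.48,2.90
arable,organic_perennial,emission,component,0.00,2.53,0.00,2.53,0.67,2.09
arable,mineral_all_crops,emission,component,0.00,0.47,0.00,0.47,0.25,0.03
arable,total,emission,category_total,2.80,5.98,3.47,12.24,3.54,0.55
forest,timber_mineral,emission,component,0.00,44.75,0.00,44.75,3.12,0.26
forest,timber_drained_peat,emission,component,0.00,8.84,0.00,8.84,0.49,0.24
forest,timber_total,emission,subtotal,0.00,53.60,0.00,53.60,3.16,0.25
forest,energywood_mineral,emission,component,0.00,5.23,0.00,5.23,0.89,0.03
forest,energywood_drained_peat,emission,component,0.00,0.99,0.00,0.99,0.14,0.03
forest,energywood_total,emission,subtotal,0.00,6.22,0.00,6.22,0.90,0.03
forest,harvest_total,emission,subtotal,0.00,59.82,0.00,59.82,3.29,0.28
forest,drained_peat_soil,emission,component,0.35,0.00,1.44,1.79,3.52,0.05
forest,total,emission,category_total,0.35,59.82,1.44,61.61,4.81,0.29
forest,ecosystems_mineral,sink,component,0.00,-79.87,0.00,-79.87,12.20,-0.38
forest,ecosystems_drained_peat,sink,component,0.00,-9.41,0.00,-9.41,6.10,-0.04
forest,total,sink,category_total,0.00,-89.28,0.00,-89.28,13.70,-0.42
forest,net,net,category_net,0.35,-29.47,1.44,-27.68,10.30,-0.13
waterbody,rivers,emission,component,0.00,7.33,0.00,7.33,1.20,5.28
waterbody,lakes,emission,component,0.86,5.16,0.00,6.02,1.50,0.19
waterbody,total,emission,category_total,0.86,12.49,0.00,13.35,1.92,0.39
wetland,peat_production,emission,component,0.06,1.80,0.09,1.95,0.39,1.90
wetland,undrained_mires_soil,emission,component,11.48,0.00,0.84,12.32,1.79,0.40
wetland,total,emission,category_total,11.54,1.80,0.93,14.27,1.84,0.45
wetland,mires_ecosystems,sink,component,0.00,-3.91,0.00,-3.91,0.40,0.00
wetland,total,sink,category_total,0.00,-3.91,0.00,-3.91,0.40,0.00
wetland,net,net,category_net,11.54,-2.11,0.93,10.36,4.40,0.34
national,total,emission,national,17.63,123.43,6.10,147.16,6.83,0.48
national,net,net,national,17.63,30.23,6.10,53.9,15.30,0.18
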