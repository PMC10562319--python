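category,subcategory,area_km2,level
artificial,all,7973,category_total
arable,livestock_production,1986,component
arable,organic_annual,958,component
arable,organic_perennial,1212,component
arable,mineral_all_crops,18265,component
arable,field_cultivation,20435,subtotal
arable,all,22537,category_total
forest,mineral_soil,174405,component
forest,drained_peatland,36725,component
forest,all,211130,category_total
waterbody,river,1388,component
waterbody,lakes,32510,component
waterbody,all,33896,category_total
wetland,peat_production,1026,component
wetland,undrained_mires,30508,component
wetland,all,31534,category_total
total,all,306954,grand_total
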