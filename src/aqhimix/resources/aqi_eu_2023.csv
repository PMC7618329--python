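pollutant,band,conc_low,conc_high
pm25,1,0,10
pm25,2,10,20
pm25,3,20,25
pm25,4,25,50
pm25,5,50,75
pm25,6,75,800
o3,1,0,50
o3,2,50,100
o3,3,100,130
o3,4,130,240
o3,5,240,380
o3,6,380,800
no2,1,0,40
no2,2,40,90
no2,3,90,120
no2,4,120,230
no2,5,230,340
no2,6,340,1000
so2,1,0,100
so2,2,100,200
so2,3,200,350
so2,4,350,500
so2,5,500,750
so2,6,750,1250
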