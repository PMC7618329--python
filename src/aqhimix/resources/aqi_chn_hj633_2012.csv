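pollutant,avg_window,conc,iaqi
pm25,24h,0,0
pm25,24h,35,50
pm25,24h,75,100
pm25,24h,115,150
pm25,24h,150,200
pm25,24h,250,300
pm25,24h,350,400
pm25,24h,500,500
o3,8h,0,0
o3,8h,100,50
o3,8h,160,100
o3,8h,215,150
o3,8h,265,200
o3,8h,800,300
no2,24h,0,0
no2,24h,40,50
no2,24h,80,100
no2,24h,180,150
no2,24h,280,200
no2,24h,565,300
no2,24h,750,400
no2,24h,940,500
so2,24h,0,0
so2,24h,50,50
so2,24h,150,100
so2,24h,475,150
so2,24h,800,200
so2,24h,1600,300
so2,24h,2100,400
so2,24h,2620,500
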