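pollutant,units,avg_window,truncate_decimals,conc_low,conc_high,aqi_low,aqi_high
pm25,ug/m3,24h,1,0.0,9.0,0,50
pm25,ug/m3,24h,1,9.1,35.4,51,100
pm25,ug/m3,24h,1,35.5,55.4,101,150
pm25,ug/m3,24h,1,55.5,125.4,151,200
pm25,ug/m3,24h,1,125.5,225.4,201,300
pm25,ug/m3,24h,1,225.5,325.4,301,500
o3,ppm,8h,3,0.000,0.054,0,50
o3,ppm,8h,3,0.055,0.070,51,100
o3,ppm,8h,3,0.071,0.085,101,150
o3,ppm,8h,3,0.086,0.105,151,200
o3,ppm,8h,3,0.106,0.200,201,300
no2,ppb,1h,0,0,53,0,50
no2,ppb,1h,0,54,100,51,100
no2,ppb,1h,0,101,360,101,150
no2,ppb,1h,0,361,649,151,200
no2,ppb,1h,0,650,1249,201,300
no2,ppb,1h,0,1250,2049,301,500
so2,ppb,1h,0,0,35,0,50
so2,ppb,1h,0,36,75,51,100
so2,ppb,1h,0,76,185,101,150
so2,ppb,1h,0,186,304,151,200
so2,ppb,1h,0,305,604,201,300
so2,ppb,24h,0,605,1004,301,500
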