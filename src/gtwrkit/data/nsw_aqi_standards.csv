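pollutant,averaging_period_hours,standard_concentration,units
CO,8,9.0,ppm
NO2,1,0.12,ppm
O3_1h,1,0.10,ppm
O3_4h,4,0.08,ppm
SO2,1,0.20,ppm
PM10,24,50,ug/m3
PM2.5,24,25,ug/m3
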