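label,date,time_utc,depth_km,depth_manual,magnitude,lon,lat,dist_cam1_km
Bad Ems,2009-09-10,12:36:21.70,5.0,1,3.2,7.72,50.40,40
Polch,2009-09-12,04:26:57.8,3.2,0,0.9,7.33,50.31,17
Nickenich,2009-09-12,22:57:19.2,2.8,0,0.4,7.32,50.42,13
Ochtendung,2009-09-15,23:06:23.0,3.0,0,0.6,7.41,50.36,20
Plaidt,2009-09-29,04:38:26.4,2.1,0,0.5,7.38,50.38,17
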