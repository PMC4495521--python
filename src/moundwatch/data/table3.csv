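label,date,time_utc,depth_km,depth_manual,magnitude,lon,lat,dist_cam1_km
Polch,2010-06-09,03:31:25.0,3.4,0,0.1,7.33,50.30,18
Koblenz,2010-06-13,14:46:34.7,5.0,1,0.8,7.56,50.34,30
Nickenich,2010-06-13,20:40:15.2,15.5,0,0.7,7.32,50.39,18
Plaidt,2010-06-14,12:32:30.9,6.4,0,0.9,7.34,50.40,14
Plaidt,2010-06-14,20:41:47.4,5.3,0,0.8,7.35,50.39,15
Kruft,2010-06-26,05:23:34.7,29.8,0,0.9,7.36,50.39,15
S. Nickenich,2010-06-26,05:24:18.6,15.2,0,0.6,7.32,50.39,13
Winningen,2010-06-26,08:15:56.3,2.1,0,0.6,7.51,50.32,28
N. Ochtendung,2010-06-27,14:27:27.1,2.1,0,0.6,7.39,50.37,18
E. Kruft,2010-06-27,15:04:37.7,2.1,0,0.6,7.35,50.38,15
Boppard,2010-06-29,05:59:34.0,2.1,0,0.2,7.62,50.23,39
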