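label,date,time_utc,depth_km,depth_manual,magnitude,lon,lat,dist_cam1_km,dist_cam2_km
Bad Ems,2009-09-10,12:36:21.70,5,1,3.2,7.72,50.40,40,22
Kruft,2010-04-11,11:16:16.50,10,1,2.9,7.34,50.40,14,10
Ochtendung,2011-08-05,09:29:37.05,10,1,2.3,7.38,50.36,15,8
Plaidt,2012-02-21,02:34:57.62,11,0,2.5,7.38,50.38,17,6
Kobern,2012-03-12,19:00:42.66,12,0,2.7,7.43,50.33,22,1
Ochtendung,2012-03-29,01:23:41.06,10,1,2.2,7.41,50.34,20,2
Plaidt,2012-05-22,00:08:47.98,10,1,2.3,7.37,50.37,17,6
Lonnig,2012-11-15,16:40:24.62,10,1,2.4,7.41,50.32,21,4
Lonnig,2012-11-22,15:43:15.90,10,1,2.8,7.41,50.32,21,4
Winningen,2012-12-16,05:54:35.40,6.9,0,2.2,7.53,50.30,30,8
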