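id,depth_m,latitude,longitude,date,duration_h,orientation,current_cm_s,temperature_c,salinity_psu,study
1,532,36.91761,21.59818,2008-10-15,6,horizontal,,14.2,,this_study
2,737,36.91420,21.56850,2008-10-14,1.83,horizontal,,13.9,,this_study
3,943,36.90412,21.56541,2008-10-16,3.64,horizontal,,13.8,,this_study
4,1346,37.08767,21.31767,2011-02-02,4,vertical,2.7,13.8,38.7,this_study
5,1823,36.93517,21.43233,2011-01-28,3.26,vertical,5.7,13.8,38.7,this_study
6,3396,36.47450,15.84533,2011-01-24,17,vertical,7.9,14.0,38.7,this_study
7,4204,36.61898,21.48337,2009-12-14,17.3,vertical,17.9,14.2,38.7,this_study
8,5111,36.55050,21.11617,2011-01-30,4.1,vertical,2.4,14.3,38.7,this_study
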