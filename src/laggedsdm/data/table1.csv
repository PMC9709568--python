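winter,survey,session,dates,total_effort_km,good_effort_km,n_individuals,n_sightings
2020,CAPECET,1,"11, 24, 26 Jan 2020",1748,1410,141,16
2020,CAPECET,2,"5-6 Feb 2020",1709,1098,138,32
2020,SPEE,5,"12 Feb 2020",3583,3565,743,135
2020,CAPECET,3,"23-24 Feb 2020",1422,785,45,7
2020,CAPECET,4,"12-13 Mar 2020",1774,1768,690,86
2021,SAMM,1,"11, 18, 25 Jan; 5, 13, 25 Feb; 3, 7, 9, 16, 25 Mar 2021",4211,4096,1208,135
2021,SPEE,9,"10, 25 Feb; 23-25 Mar 2021",1738,1660,735,95
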