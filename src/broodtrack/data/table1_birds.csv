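# Source: published per-bird tracking summary table for the north Wales breeding
# curlew GPS cohort (2016, 2018, 2019); distances in km from the tagging location.
# Birds without analyzable data carry NA values.
year,site,tag_id,sex,n_days,n_relocations,start_date,end_date,mean_km,max_km,mean_incubation_km
2016,Snw,303O_NN,M,30.3,2796,2016-05-07,2016-06-06,2.22,7.17,NA
2016,Snw,301O_NG,M,16.1,1512,2016-05-08,2016-05-24,1.54,2.03,0.11
2016,Snw,285O_NO,M,26.7,2530,2016-05-08,2016-06-04,2.28,12.00,0.16
2018,Snw,341O_RR,M,60.2,2108,2018-05-11,2018-07-10,16.87,40.75,NA
2018,Snw,355O_RG,F,47.3,2946,2018-05-13,2018-06-29,1.48,4.45,0.24
2018,Snw,350O_BB,M,NA,NA,2018-05-13,NA,NA,NA,NA
2018,Snw,352O_OO,M,23,1744,2018-05-16,2018-06-08,1.71,2.12,0.07
2018,Ang,339O_OW,M,96.1,9069,2018-05-05,2018-08-09,3.31,6.89,0.13
2018,Ang,340O_GG,M,0.3,31,2018-05-12,2018-05-12,3.73,11.44,NA
2019,Snw,354W_BO,F,51.4,4641,2019-04-17,2019-06-08,1.56,4.36,0.58
2019,Snw,346W_OW,F,25.7,2377,2019-04-18,2019-05-14,1.39,1.93,0.25
2019,Snw,709W_RB,M,69.4,6422,2019-04-18,2019-06-26,2.08,21.91,0.70
2019,Snw,016W_GO,F,16.4,1431,2019-04-18,2019-05-04,2.16,4.02,NA
2019,Snw,351O_RW,M,67.3,6219,2019-04-18,2019-06-24,1.77,16.41,0.22
2019,Snw,348W_OG,M,31,1045,2019-04-23,2019-05-24,1.75,10.04,0.41
2019,Snw,347W_OR,F,61,5302,2019-04-23,2019-06-23,4.80,27.78,NA
2019,Snw,342W_BW,M,24.5,2273,2019-04-23,2019-05-18,1.43,4.11,NA
2019,Ang,007O_BW,F,50.1,4244,2019-04-09,2019-05-29,1.38,2.32,0.24
2019,Ang,087O_RN,M,58.7,5263,2019-04-09,2019-06-07,1.34,2.25,0.18
2019,Ang,052O_GR,M,47.8,4401,2019-04-10,2019-05-28,1.71,2.68,0.19
2019,Ang,085O_RO,M,43.3,3507,2019-04-11,2019-05-24,2.31,14.61,0.92
2019,Ang,211O_OW,M,34.6,3215,2019-04-13,2019-05-17,2.12,3.45,0.12
2019,Ang,041O_BO,F,NA,NA,2019-04-17,NA,NA,NA,NA
2019,Clw,002O_GO,M,59.6,5144,2019-05-02,2019-06-30,5.49,9.27,0.57
2019,Clw,165W_RR,M,54.8,4916,2019-05-02,2019-06-26,2.71,9.22,0.73
2019,Clw,678O_RB,M,NA,NA,2019-05-03,NA,NA,NA,NA
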