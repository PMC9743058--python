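# Source: published breeding-attempt outcome table for the north Wales breeding
# curlew GPS cohort; one row per tracked bird with analyzable data.
# Sex codes are kept exactly as printed there (007O_BW prints M here, F in the
# tracking-summary table). status_at_end: breeding status when tagging ended.
tag_id,sex,year,site,nonbreeder,status_at_end
285O_NO,M,2016,Snw,No,None
301O_NG,M,2016,Snw,No,CG
303O_NN,M,2016,Snw,Yes,None
355O_RG,F,2018,Snw,No,None
341O_RR,M,2018,Snw,Yes,None
352O_OO,M,2018,Snw,No,I2
339O_OW,M,2018,Ang,No,None
340O_GG,M,2018,Ang,Yes,None
016W_GO,F,2019,Snw,Yes,None
346W_OW,F,2019,Snw,No,None
347W_OR,F,2019,Snw,Yes,None
354W_BO,F,2019,Snw,No,I2
342W_BW,M,2019,Snw,Yes,None
348W_OG,M,2019,Snw,No,None
351O_RW,M,2019,Snw,No,None
709W_RB,M,2019,Snw,No,None
007O_BW,M,2019,Ang,No,I2
052O_GR,M,2019,Ang,No,I3
085O_RO,M,2019,Ang,No,None
087O_RN,M,2019,Ang,No,I2
211O_OW,M,2019,Ang,No,I1
002O_GO,M,2019,Clw,No,CG
165W_RR,M,2019,Clw,No,None
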