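# Source: published breeding-attempt outcome table for the north Wales breeding
# curlew GPS cohort; one row per nesting (incubation) attempt.
# interval_days: printed nesting interval; open_ended: printed with a trailing
# '+' (tag record ends inside the interval). fate: Y = hatched, N = failed
# during incubation, OU = outcome uncertain (tag fell off; right censored).
# 351O_RW attempt 2 prints '4+' yet fate N, kept as printed.
tag_id,attempt_index,interval_days,open_ended,fate
285O_NO,1,6,False,N
301O_NG,1,8,False,Y
355O_RG,1,4,False,N
352O_OO,1,15,False,N
352O_OO,2,7,True,OU
339O_OW,1,30,False,Y
346W_OW,1,6,False,N
354W_BO,1,5,False,N
354W_BO,2,32,True,OU
348W_OG,1,8,False,N
351O_RW,1,6,False,N
351O_RW,2,4,True,N
709W_RB,1,12,False,N
007O_BW,1,15,False,N
007O_BW,2,10,True,OU
052O_GR,1,5,False,N
052O_GR,2,4,False,N
052O_GR,3,4,True,OU
085O_RO,1,8,False,N
087O_RN,1,13,False,N
087O_RN,2,19,True,OU
211O_OW,1,17,True,OU
002O_GO,1,33,False,Y
165W_RR,1,6,False,N
165W_RR,2,17,False,N
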