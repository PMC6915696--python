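label,table,mean_q,sd_q,cv_percent,re_percent
avgQ48a_1600pM,1,48.44,0.36,0.75,1.01
avgQ48a_1280pM,1,48.29,1.27,2.63,0.69
avgQ48a_960pM,1,51.01,1.67,3.28,6.36
avgQ48a_640pM,1,51.14,1.41,2.76,6.64
avgQ48a_320pM,1,53.9,0.99,1.83,12.39
avgQ48a,2,51.75,1.75,3.37,7.9
avgQ48b,2,50.71,0.22,0.44,5.75
avgQ48c,2,50.28,1.68,3.34,4.9
avgQ38,3,42.26,1.5,3.55,11.2
avgQ40.5,3,44.69,1.29,2.89,10.38
avgQ43,3,48.48,0.51,1.05,12.74
avgQ45.5,3,49.54,1.08,2.19,8.93
avgQ50.5,3,54.08,1.71,3.17,7.12
avgQ53,3,56.09,1.36,2.43,5.84
avgQ55.5,3,59.52,0.14,0.23,7.21
avgQ58,3,60.94,1.51,2.53,5.06
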