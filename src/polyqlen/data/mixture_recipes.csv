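label,table,total_concentration_pM,q_length,fraction
avgQ48a_1600pM,1,1600,25,0.18
avgQ48a_1600pM,1,1600,38,0.21
avgQ48a_1600pM,1,1600,48,0.21
avgQ48a_1600pM,1,1600,55,0.2
avgQ48a_1600pM,1,1600,72,0.2
avgQ48a_1280pM,1,1280,25,0.18
avgQ48a_1280pM,1,1280,38,0.21
avgQ48a_1280pM,1,1280,48,0.21
avgQ48a_1280pM,1,1280,55,0.2
avgQ48a_1280pM,1,1280,72,0.2
avgQ48a_960pM,1,960,25,0.18
avgQ48a_960pM,1,960,38,0.21
avgQ48a_960pM,1,960,48,0.21
avgQ48a_960pM,1,960,55,0.2
avgQ48a_960pM,1,960,72,0.2
avgQ48a_640pM,1,640,25,0.18
avgQ48a_640pM,1,640,38,0.21
avgQ48a_640pM,1,640,48,0.21
avgQ48a_640pM,1,640,55,0.2
avgQ48a_640pM,1,640,72,0.2
avgQ48a_320pM,1,320,25,0.18
avgQ48a_320pM,1,320,38,0.21
avgQ48a_320pM,1,320,48,0.21
avgQ48a_320pM,1,320,55,0.2
avgQ48a_320pM,1,320,72,0.2
avgQ48a,2,1280,25,0.18
avgQ48a,2,1280,38,0.21
avgQ48a,2,1280,48,0.21
avgQ48a,2,1280,55,0.2
avgQ48a,2,1280,72,0.2
avgQ48b,2,1280,25,0.09
avgQ48b,2,1280,38,0.2
avgQ48b,2,1280,48,0.33
avgQ48b,2,1280,55,0.3
avgQ48b,2,1280,72,0.08
avgQ48c,2,1280,25,0.12
avgQ48c,2,1280,38,0.34
avgQ48c,2,1280,48,0.18
avgQ48c,2,1280,55,0.15
avgQ48c,2,1280,72,0.21
avgQ38,3,1280,25,0.45
avgQ38,3,1280,38,0.21
avgQ38,3,1280,48,0.16
avgQ38,3,1280,55,0.11
avgQ38,3,1280,72,0.07
avgQ40.5,3,1280,25,0.37
avgQ40.5,3,1280,38,0.21
avgQ40.5,3,1280,48,0.22
avgQ40.5,3,1280,55,0.1
avgQ40.5,3,1280,72,0.1
avgQ43,3,1280,25,0.38
avgQ43,3,1280,38,0.14
avgQ43,3,1280,48,0.11
avgQ43,3,1280,55,0.22
avgQ43,3,1280,72,0.15
avgQ45.5,3,1280,25,0.23
avgQ45.5,3,1280,38,0.25
avgQ45.5,3,1280,48,0.18
avgQ45.5,3,1280,55,0.17
avgQ45.5,3,1280,72,0.17
avgQ50.5,3,1280,25,0.15
avgQ50.5,3,1280,38,0.15
avgQ50.5,3,1280,48,0.22
avgQ50.5,3,1280,55,0.24
avgQ50.5,3,1280,72,0.24
avgQ53,3,1280,25,0.1
avgQ53,3,1280,38,0.22
avgQ53,3,1280,48,0.1
avgQ53,3,1280,55,0.26
avgQ53,3,1280,72,0.32
avgQ55.5,3,1280,25,0.05
avgQ55.5,3,1280,38,0.13
avgQ55.5,3,1280,48,0.27
avgQ55.5,3,1280,55,0.19
avgQ55.5,3,1280,72,0.36
avgQ58,3,1280,25,0.1
avgQ58,3,1280,38,0.05
avgQ58,3,1280,48,0.09
avgQ58,3,1280,55,0.32
avgQ58,3,1280,72,0.44
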