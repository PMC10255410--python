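run_index,nature,paradigm,t1_class,t2_class
1,baseline,eyes_open,,
2,baseline,eyes_closed,,
3,ME,LR,left_fist,right_fist
4,MI,LR,left_fist,right_fist
5,ME,FF,both_fists,both_feet
6,MI,FF,both_fists,both_feet
7,ME,LR,left_fist,right_fist
8,MI,LR,left_fist,right_fist
9,ME,FF,both_fists,both_feet
10,MI,FF,both_fists,both_feet
11,ME,LR,left_fist,right_fist
12,MI,LR,left_fist,right_fist
13,ME,FF,both_fists,both_feet
14,MI,FF,both_fists,both_feet
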