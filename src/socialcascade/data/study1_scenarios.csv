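scenario_id,study,predecessors,private_signal,reliability,prior_A
s1-01,study1,EQ:A,a,2/3,0.5
s1-02,study1,EQ:A;EQ:A,a,2/3,0.5
s1-03,study1,EQ:A;EQ:B,a,2/3,0.5
s1-04,study1,EQ:A;EQ:A;EQ:A,a,2/3,0.5
s1-05,study1,EQ:A;EQ:B;EQ:A,a,2/3,0.5
s1-06,study1,EQ:A;EQ:A,b,2/3,0.5
s1-07,study1,EQ:A;EQ:B,b,2/3,0.5
s1-08,study1,EQ:A;EQ:A;EQ:A,b,2/3,0.5
s1-09,study1,EQ:A;EQ:B;EQ:B,b,2/3,0.5
s1-10,study1,EQ:A,b,2/3,0.5
s1-11,study1,EQ:A;EQ:B;EQ:B,a,2/3,0.5
s1-12,study1,EQ:A;EQ:B;EQ:A,b,2/3,0.5
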