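scenario_id,study,predecessors,private_signal,reliability,prior_A
s2-01,study2,EQ:A;EQ:B,a,2/3,0.5
s2-02,study2,EQ:A;EQ:B,b,2/3,0.5
s2-03,study2,EQ:A;EQ:A,b,2/3,0.5
s2-04,study2,EQ:A;EQ:A;EQ:A,b,2/3,0.5
s2-05,study2,HR:A;EQ:B,a,2/3,0.5
s2-06,study2,EQ:A;HR:B,b,2/3,0.5
s2-07,study2,HR:A;EQ:B,b,2/3,0.5
s2-08,study2,EQ:A;HR:B,a,2/3,0.5
s2-09,study2,HR:A;EQ:A,b,2/3,0.5
s2-10,study2,EQ:A;HR:A,b,2/3,0.5
s2-11,study2,HR:A;EQ:A;EQ:A,b,2/3,0.5
s2-12,study2,EQ:A;HR:A;EQ:A,b,2/3,0.5
s2-13,study2,EQ:A;EQ:A;HR:A,b,2/3,0.5
s2-14,study2,EQ:A,a,2/3,0.5
s2-15,study2,EQ:A;EQ:B;EQ:A,a,2/3,0.5
s2-16,study2,EQ:A;EQ:B;EQ:B,b,2/3,0.5
s2-17,study2,HR:A,a,2/3,0.5
s2-18,study2,HR:A;EQ:B;EQ:A,a,2/3,0.5
s2-19,study2,EQ:A;EQ:B;HR:A,a,2/3,0.5
s2-20,study2,EQ:A;HR:B;EQ:B,b,2/3,0.5
s2-21,study2,EQ:A;EQ:B;HR:B,b,2/3,0.5
s2-22,study2,EQ:A;HR:B;EQ:A,a,2/3,0.5
s2-23,study2,HR:A;EQ:B;EQ:B,b,2/3,0.5
s2-24,study2,EQ:A;EQ:A,a,2/3,0.5
s2-25,study2,EQ:A;EQ:A;EQ:A,a,2/3,0.5
s2-26,study2,HR:A;EQ:A,a,2/3,0.5
s2-27,study2,EQ:A;HR:A,a,2/3,0.5
s2-28,study2,HR:A;EQ:A;EQ:A,a,2/3,0.5
s2-29,study2,EQ:A;HR:A;EQ:A,a,2/3,0.5
s2-30,study2,EQ:A;EQ:A;HR:A,a,2/3,0.5
s2-31,study2,EQ:A,b,2/3,0.5
s2-32,study2,EQ:A;EQ:B;EQ:B,a,2/3,0.5
s2-33,study2,EQ:A;EQ:B;EQ:A,b,2/3,0.5
s2-34,study2,HR:A;EQ:B;EQ:B,a,2/3,0.5
s2-35,study2,EQ:A;HR:B;EQ:A,b,2/3,0.5
s2-36,study2,HR:A,b,2/3,0.5
s2-37,study2,EQ:A;HR:B;EQ:B,a,2/3,0.5
s2-38,study2,EQ:A;EQ:B;HR:B,a,2/3,0.5
s2-39,study2,HR:A;EQ:B;EQ:A,b,2/3,0.5
s2-40,study2,EQ:A;EQ:B;HR:A,b,2/3,0.5
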