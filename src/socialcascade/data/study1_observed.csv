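scenario_id,printed_posterior,printed_favored,pct_choices,mean_judgment
s1-01,0.80,A,91.3,0.66
s1-02,0.89,A,90.0,0.74
s1-03,0.67,A,91.1,0.62
s1-04,0.89,A,85.0,0.75
s1-05,0.80,A,85.0,0.69
s1-06,0.67,A,71.3,0.54
s1-07,0.67,B,95.0,0.66
s1-08,0.67,A,79.7,0.65
s1-09,0.80,B,93.8,0.74
s1-10,0.50,none,90.0,0.60
s1-11,0.50,none,65.0,0.60
s1-12,0.50,none,84.8,0.58
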