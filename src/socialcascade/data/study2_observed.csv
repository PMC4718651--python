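scenario_id,printed_posterior,printed_favored,pct_choices,mean_judgment,printed_condition
s2-01,0.67,A,95.0,0.70,baseline
s2-02,0.67,B,92.5,0.66,baseline
s2-03,0.67,A,75.0,0.60,baseline
s2-04,0.67,A,75.0,0.66,baseline
s2-05,0.67,A,95.0,0.72,md_supports
s2-06,0.67,B,92.5,0.68,md_supports
s2-07,0.67,B,87.5,0.61,md_opposes
s2-08,0.67,A,82.5,0.64,md_opposes
s2-09,0.67,A,82.5,0.67,md_opposes
s2-10,0.67,A,82.5,0.65,md_opposes
s2-11,0.67,A,87.5,0.70,md_opposes
s2-12,0.67,A,87.5,0.72,md_opposes
s2-13,0.67,A,85.0,0.71,md_opposes
s2-14,0.80,A,97.5,0.80,baseline
s2-15,0.80,A,95.0,0.77,baseline
s2-16,0.80,B,97.5,0.75,baseline
s2-17,0.80,A,97.5,0.83,md_supports
s2-18,0.80,A,95.0,0.79,md_supports
s2-19,0.80,A,97.5,0.79,md_supports
s2-20,0.80,B,95.0,0.76,md_supports
s2-21,0.80,B,97.5,0.77,md_supports
s2-22,0.80,A,90.0,0.72,md_opposes
s2-23,0.80,B,82.5,0.63,md_opposes
s2-24,0.89,A,100.0,0.84,baseline
s2-25,0.89,A,97.5,0.86,baseline
s2-26,0.89,A,100.0,0.87,md_supports
s2-27,0.89,A,100.0,0.85,md_supports
s2-28,0.89,A,100.0,0.89,md_supports
s2-29,0.89,A,100.0,0.88,md_supports
s2-30,0.89,A,100.0,0.88,md_supports
s2-31,0.50,none,70.0,0.62,baseline
s2-32,0.50,none,40.0,0.63,baseline
s2-33,0.50,none,60.0,0.66,baseline
s2-34,0.50,none,75.0,0.68,md_supports
s2-35,0.50,none,60.0,0.69,md_supports
s2-36,0.50,none,37.5,0.62,md_opposes
s2-37,0.50,none,40.0,0.63,md_opposes
s2-38,0.50,none,30.0,0.66,md_opposes
s2-39,0.50,none,47.5,0.66,md_opposes
s2-40,0.50,none,37.5,0.68,md_opposes
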