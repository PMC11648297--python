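outcome_type,comparator_type,size_bin,median,q3
general,,,0.13,0.53
objective,pharm_vs_placebo,<50,0.0007,0.01
objective,pharm_vs_pharm,<50,0.0004,0.005
objective,nonpharm_vs_any,<50,0.0007,0.01
semi-objective,pharm_vs_placebo,<50,0.06,0.28
semi-objective,pharm_vs_pharm,<50,0.04,0.16
semi-objective,nonpharm_vs_any,<50,0.06,0.29
subjective,pharm_vs_placebo,<50,0.25,0.53
subjective,pharm_vs_pharm,<50,0.16,0.32
subjective,nonpharm_vs_any,<50,0.24,0.55
objective,pharm_vs_placebo,50-200,0.0007,0.01
objective,pharm_vs_pharm,50-200,0.0004,0.005
objective,nonpharm_vs_any,50-200,0.0007,0.01
semi-objective,pharm_vs_placebo,50-200,0.06,0.27
semi-objective,pharm_vs_pharm,50-200,0.04,0.16
semi-objective,nonpharm_vs_any,50-200,0.06,0.29
subjective,pharm_vs_placebo,50-200,0.25,0.52
subjective,pharm_vs_pharm,50-200,0.16,0.32
subjective,nonpharm_vs_any,50-200,0.23,0.55
objective,pharm_vs_placebo,>200,0.0008,0.01
objective,pharm_vs_pharm,>200,0.0005,0.006
objective,nonpharm_vs_any,>200,0.0007,0.01
semi-objective,pharm_vs_placebo,>200,0.07,0.30
semi-objective,pharm_vs_pharm,>200,0.04,0.18
semi-objective,nonpharm_vs_any,>200,0.06,0.33
subjective,pharm_vs_placebo,>200,0.28,0.56
subjective,pharm_vs_pharm,>200,0.18,0.35
subjective,nonpharm_vs_any,>200,0.26,0.58
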