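country_id,age_group,u5mr,malaria_fraction,aids,diarrhea,measles,meningitis,malaria,pneumonia,injury,other_infectious,non_infectious
synth_hm1,child,92,0.18,0.04,0.18,0.03,0.05,0.22,0.24,0.05,0.11,0.08
synth_hm2,child,64,0.24,0.05,0.16,0.02,0.05,0.26,0.22,0.05,0.11,0.08
synth_hm3,child,48,0.09,0.06,0.19,0.03,0.06,0.12,0.26,0.06,0.12,0.10
synth_hn1,child,55,0.01,0.06,0.21,0.04,0.06,0.02,0.28,0.07,0.13,0.13
synth_hn2,child,41,0.03,0.05,0.20,0.03,0.06,0.04,0.27,0.08,0.13,0.14
synth_hn3,child,38,0.00,0.04,0.22,0.04,0.07,0.00,0.26,0.08,0.14,0.15
synth_mm1,child,33,0.02,0.03,0.17,0.02,0.06,0.03,0.24,0.11,0.14,0.20
synth_mm2,child,27,0.06,0.03,0.15,0.01,0.05,0.07,0.22,0.13,0.13,0.21
synth_mm3,child,21,0.00,0.02,0.13,0.01,0.05,0.00,0.20,0.16,0.13,0.30
synth_lo1,child,14,0.00,0.01,0.10,0.00,0.04,0.00,0.17,0.20,0.12,0.36
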