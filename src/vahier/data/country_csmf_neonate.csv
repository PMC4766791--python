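country_id,age_group,u5mr,malaria_fraction,preterm_delivery,birth_asphyxia,congenital_malformation,meningitis,pneumonia,sepsis
synth_hm1,neonate,92,0.18,0.30,0.26,0.05,0.05,0.12,0.22
synth_hm2,neonate,64,0.24,0.33,0.24,0.06,0.06,0.10,0.21
synth_hm3,neonate,48,0.09,0.31,0.27,0.07,0.05,0.11,0.19
synth_hn1,neonate,55,0.01,0.35,0.25,0.08,0.04,0.10,0.18
synth_hn2,neonate,41,0.03,0.32,0.28,0.09,0.04,0.09,0.18
synth_hn3,neonate,38,0.00,0.34,0.24,0.10,0.05,0.10,0.17
synth_mm1,neonate,33,0.02,0.36,0.22,0.13,0.04,0.09,0.16
synth_mm2,neonate,27,0.06,0.38,0.21,0.14,0.03,0.08,0.16
synth_mm3,neonate,21,0.00,0.40,0.20,0.16,0.03,0.07,0.14
synth_lo1,neonate,14,0.00,0.42,0.18,0.20,0.02,0.06,0.12
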