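stage,t0_c,t0_se,k_dd,k_se
larvae_after_overwintering,9.72,0.62,757.92,55.34
pupae,13.38,0.35,234.27,7.98
egg,9.62,0.29,137.16,2.78
larvae_before_overwintering,8.94,0.77,568.84,66.15
complete_generation,9.95,0.61,1698.18,48.18
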