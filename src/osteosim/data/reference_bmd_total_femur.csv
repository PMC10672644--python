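population,age_range_young,age_range_ref,bmd_s,bmd_sd,bmd_ref,n_young,n_ref
non_hispanic_white,20-29,40-59,0.942,0.122,0.885,409,894
non_hispanic_black,20-29,40-59,1.026,0.134,0.990,492,645
mexican_american,20-29,40-59,0.950,0.113,0.919,479,494
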