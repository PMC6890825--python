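comparison,n_universe,size_a,size_b,overlap
adult_long_insular_vs_fetal_granular_up,20778,1273,733,160
adult_short_insular_vs_fetal_dysgranular_up,20778,2697,881,407
adult_long_vs_short_insular_up,20778,1273,2697,766
adult_long_vs_short_insular_top20,20778,20,20,8
fetal_granular_vs_dysgranular_up,20778,733,881,213
fetal_granular_vs_dysgranular_top20,20778,20,20,11
adult_vs_fetal_claustrum_up,20778,9591,379,261
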