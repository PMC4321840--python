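# Two-pool MT parameters at 3 T.
# white_matter / gray_matter: literature two-pool values for human brain;
# white-matter T2 of the free pool is the observed 85 ms value.
# agar: 10% agar gel relaxation times (T1 = 1700 ms, T2 = 36 ms). Its MT
#   parameters (F, kr, T2r) are synthetic placeholders chosen to give a
#   strong, homogeneous MT effect -- agar exchange parameters were not
#   measured here.
# saline / csf: free water with no macromolecular pool (F = 0), hence no
#   MT effect; negative controls.

[white_matter]
t1_free = 1.1
t2_free = 0.085
t1_restricted = 1.0
t2_restricted = 13e-6
pool_ratio_F = 0.14
exchange_rate_kr = 23.0
g_zero = 1.4e-5

[gray_matter]
t1_free = 1.8
t2_free = 0.099
t1_restricted = 1.0
t2_restricted = 9e-6
pool_ratio_F = 0.05
exchange_rate_kr = 40.0
g_zero = 1.4e-5

[agar]
t1_free = 1.7
t2_free = 0.036
t1_restricted = 1.0
t2_restricted = 10e-6
pool_ratio_F = 0.10
exchange_rate_kr = 40.0
g_zero = 1.4e-5

[saline]
t1_free = 3.0
t2_free = 2.0
t1_restricted = 1.0
t2_restricted = 10e-6
pool_ratio_F = 0.0
exchange_rate_kr = 0.0
g_zero = 0.0

[csf]
t1_free = 4.0
t2_free = 2.0
t1_restricted = 1.0
t2_restricted = 10e-6
pool_ratio_F = 0.0
exchange_rate_kr = 0.0
g_zero = 0.0
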