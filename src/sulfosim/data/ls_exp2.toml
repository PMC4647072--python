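schema_version = 1

[parameters]
ds = 30.0
rue = 3.11
tt_offset = 565.0
la0 = 0.014
qs_ini = 1.939
a_qs = 2.207
b_qs = 0.0014
dw_fl_ini = 0.04
k = 0.75
t_base = 5.0
la_max = 0.20
k_half = 872.96
n_shape = 6.31
sla = 0.028
beta_alloc = 0.41
a_ldw_fl = 0.0092
b_ldw_fl = 0.0043
alpha_bl = 5.11
beta_bl = -0.52
s_crit_floor = 3.0
ldw_floor_threshold = 3.0
alpha_rest = 1.83
beta_rest = -0.004
eps_pot = 0.8
la_provider = "hill"
leaf_fall_provider = "exp_amplitude"

[initial_state]
la0 = 0.014
tdw_ini = 0.778
dw_fl_ini = 0.04
ldw_bl_ini = 0.589
qs_tot_ini = 1.939
a_qs = 2.207
b_qs = 0.0014
qs_bl_ini = 1.38
qs_rest_ini = 0.55
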