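schema_version = 1

[parameters]
ds = 30.0
rue = 4.59
tt_offset = 565.0
la0 = 0.014
qs_ini = 10.594
a_qs = 23.457
b_qs = 0.0026
dw_fl_ini = 0.05
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
tdw_ini = 1.031
dw_fl_ini = 0.05
ldw_bl_ini = 0.736
qs_tot_ini = 10.594
a_qs = 23.457
b_qs = 0.0026
qs_bl_ini = 7.89
qs_rest_ini = 2.26
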