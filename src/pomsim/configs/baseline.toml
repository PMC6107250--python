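# Packaged baseline: wild-type-like M. xanthus geometry and rates.
# See docs/methods.md for the provenance and units of each value.
[model]
L = 5.0
L_c = 0.7
a = 0.01
k = 100.0
kBT = 0.0041
k_on = 0.1
ka0 = 50.0
k_h = 1.0
k_off = 0.0
D_nuc = 0.1
D_clu = 0.1
gamma_c = 20.0
N_total = 100
t_min = 600.0
infinite_lattice = false
F_ext = 0.0
lambda_null = 0.0
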