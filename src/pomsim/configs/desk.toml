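# Reduced validation geometry: same physics at 40% nucleoid length and a
# third of the dimer count, with a lighter cluster so trajectories resolve
# within minutes of CPU time.  See docs/methods.md.
[model]
L = 2.0
L_c = 0.28
a = 0.01
k = 100.0
kBT = 0.0041
k_on = 0.2
ka0 = 50.0
k_h = 1.0
k_off = 0.0
D_nuc = 0.1
D_clu = 0.1
gamma_c = 5.0
N_total = 30
t_min = 200.0
infinite_lattice = false
F_ext = 0.0
lambda_null = 0.0
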