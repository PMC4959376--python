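"""Compare the MDL and NML complexity penalties as the sample grows.

MDL is the closed form (1/2)(r_x-1)(r_y-1) ln N; NML is computed from the
universal multinomial constants C^r_n and approaches MDL from below as N
grows (Laplace limit), while penalizing sparsely observed states less
harshly at small N.
"""

from threeoff2 import fixtures, mdl_pair_complexity, nml_pair_complexity, sample

net = fixtures()["chain"]
for n in (50, 500, 5000, 50_000):
    data = sample(net, n, seed=0)
    x, y = data.index_of("x"), data.index_of("z")
    k_mdl = mdl_pair_complexity(2, 2, (), n).value
    k_nml = nml_pair_complexity(data, x, y).value
    print(f"N={n:>6}  k_MDL={k_mdl:7.3f}  k_NML={k_nml:7.3f}  ratio={k_nml / k_mdl:.3f}")
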