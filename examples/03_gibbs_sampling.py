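"""Modified Gibbs sampling of the toggle switch.

The sampler draws each coordinate from a detailed-balance conditional
along a lattice line; a random rotation of the two sampling axes at every
cycle lets the chain hop between the two modes of the bimodal
distribution, which axis-aligned Gibbs does only rarely.
"""

import numpy as np

import cmenoise as cn

network, space = cn.load_builtin_model("toggle_table1_set1")
direct = cn.solve_steady_state(cn.build_generator(network, space), space)

samples = cn.mgs_sample(network, space, n=10_000, burn_in=1000, seed=7, rotate=True)
print(f"{len(samples)} samples, first 3 states:\n{samples.states[:3]}")
print(f"sample mean (u, v): {np.round(samples.mean(), 3)}")
print(f"direct mean (u, v): {np.round(direct.mean(), 3)}")
print(f"SSD sample histogram vs direct solution: {cn.ssd(samples, direct, space=space):.4f}")
print("(~1e-2: the detailed-balance approximation plus finite-sample noise)")

modes = cn.deterministic_fixed_points(network, space)
print(f"deterministic modes used for initialization: {[m.tolist() for m in modes]}")
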