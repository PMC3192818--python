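"""Extrinsic noise by convolution and by gamma parameter mixing.

Everything outside the modeled reactions is summarized as a Gaussian
distribution of shifts convolved with the intrinsic-noise distribution.
The alternative route draws the rate ratio k_s/k_d from a gamma
distribution, giving a negative-binomial mixture; fitting the convolution
width sigma to that mixture recovers the spread the parameter variation
induced.
"""

import cmenoise as cn

poisson = cn.poisson_constitutive(20.0, 1.0, 120)

wide = cn.convolve_grid(poisson, cn.ExtrinsicNoiseSpec(cov=3.0))
print(f"intrinsic SD: {poisson.std()[0]:.3f}   after sigma=3 convolution: {wide.std()[0]:.3f}")
print(f"mass conserved: {wide.mass.sum():.12f}")

mixed = cn.gamma_mixed_birth_death(alpha=20.0, theta=1.0, n_max=120)
print(f"gamma-mixed mean {mixed.mean()[0]:.2f}, variance {mixed.std()[0] ** 2:.2f} "
      "(= alpha*theta and alpha*theta*(1+theta))")

fit = cn.fit_extrinsic_sigma(poisson, mixed, fit_shift=True)
print(f"best-fit convolution width for the Gamma(20,1) mixture: sigma = {fit.sigma:.2f}")
fit2 = cn.fit_extrinsic_sigma(poisson, cn.gamma_mixed_birth_death(10.0, 2.0, 120), fit_shift=True)
print(f"best-fit width for the Gamma(10,2) mixture:            sigma = {fit2.sigma:.2f}")

# the sample route: shift exact draws instead of convolving the grid
samples = cn.SampleSet(poisson.sample_states(50_000, __import__("numpy").random.default_rng(0)))
shifted = cn.shift_samples(samples, cn.ExtrinsicNoiseSpec(cov=3.0), seed=1, round_to_lattice=True)
print(f"sample-route SSD vs grid route: {cn.ssd(shifted, wide, space=poisson.space):.2e}")
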