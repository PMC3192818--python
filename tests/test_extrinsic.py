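"""Extrinsic-noise convolution: grids, samples, gamma mixing, sigma fit."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

import cmenoise as cn
from cmenoise.network import ModelError


class TestConvolveGrid:
    def test_identity_kernel(self, toggle_set1):
        _, _, dist = toggle_set1
        out = cn.convolve_grid(dist, cn.ExtrinsicNoiseSpec(cov=0.0))
        np.testing.assert_allclose(out.mass, dist.mass, atol=1e-12)

    @pytest.mark.parametrize("cov", [1.0, 2.5, np.array([2.0, 0.5])])
    def test_mass_conserved(self, toggle_set1, cov):
        _, _, dist = toggle_set1
        out = cn.convolve_grid(dist, cn.ExtrinsicNoiseSpec(cov=cov))
        assert out.mass.sum() == pytest.approx(1.0, abs=1e-10)

    def test_direct_and_fft_agree(self, toggle_set1):
        _, _, dist = toggle_set1
        spec = cn.ExtrinsicNoiseSpec(cov=2.0)
        a = cn.convolve_grid(dist, spec, method="direct")
        b = cn.convolve_grid(dist, spec, method="fft")
        assert np.abs(a.mass - b.mass).max() < 1e-10

    def test_peaks_widen_but_barely_move(self, toggle_symmetric):
        """sigma=2 on the bimodal toggle: probability spreads (the peak
        height drops) while the interior peak locations move by less than
        one lattice unit."""
        _, space, dist = toggle_symmetric
        out = cn.convolve_grid(dist, cn.ExtrinsicNoiseSpec(cov=2.0))
        assert out.grid.max() < 0.7 * dist.grid.max()

        # mask to the u-dominant half to isolate one peak
        masked_in = dist.grid.copy()
        masked_out = out.grid.copy()
        tri = np.tri(*space.shape, k=-1) == 0
        masked_in[tri] = 0
        masked_out[tri] = 0
        p_in = np.unravel_index(np.argmax(masked_in), space.shape)
        p_out = np.unravel_index(np.argmax(masked_out), space.shape)
        assert np.abs(np.array(p_in) - np.array(p_out)).max() <= 1

    def test_commutation_of_successive_kernels(self):
        """Convolving with sigma_a then sigma_b equals one convolution
        with sqrt(a^2+b^2) away from the boundary."""
        dist = cn.poisson_constitutive(30.0, 1.0, 120)
        a = cn.convolve_grid(
            cn.convolve_grid(dist, cn.ExtrinsicNoiseSpec(cov=2.0)),
            cn.ExtrinsicNoiseSpec(cov=1.5),
        )
        b = cn.convolve_grid(dist, cn.ExtrinsicNoiseSpec(cov=np.sqrt(2.0**2 + 1.5**2)))
        assert float(np.sum((a.mass - b.mass) ** 2)) < 1e-4

    def test_background_term_and_validation(self, toggle_set1):
        _, space, dist = toggle_set1
        out = cn.convolve_grid(
            dist, cn.ExtrinsicNoiseSpec(cov=1.0, background_weight=0.1)
        )
        assert out.mass.sum() == pytest.approx(1.0, abs=1e-10)
        assert out.mass.min() >= 0.1 / space.n_states * 0.999  # uniform floor
        with pytest.raises(ModelError):
            cn.convolve_grid(dist, cn.ExtrinsicNoiseSpec(cov=1.0, background_weight=1.0))
        with pytest.raises(ModelError):
            cn.convolve_grid(dist, cn.ExtrinsicNoiseSpec(cov=np.array([[1.0, 9.0], [9.0, 1.0]])))

    def test_per_mode_covariances(self, toggle_symmetric):
        network, space, dist = toggle_symmetric
        fps = cn.deterministic_fixed_points(network, space)
        spec = cn.ExtrinsicNoiseSpec(modes=[(fps[0], 2.0), (fps[1], 0.5)])
        out = cn.convolve_grid(dist, spec)
        assert out.mass.sum() == pytest.approx(1.0, abs=1e-10)
        # the sigma=2 mode flattens while the sigma=0.5 mode keeps its peak
        assert out.grid[tuple(fps[0])] < out.grid[tuple(fps[1])]
        uniform = cn.convolve_grid(dist, cn.ExtrinsicNoiseSpec(cov=0.5))
        assert uniform.grid[tuple(fps[0])] == pytest.approx(
            uniform.grid[tuple(fps[1])], rel=1e-6
        )


class TestShiftSamples:
    def test_zero_covariance_is_identity(self, toggle_set1):
        ss = cn.SampleSet(np.array([[3, 4], [5, 6]]))
        out = cn.shift_samples(ss, cn.ExtrinsicNoiseSpec(cov=0.0), seed=0)
        np.testing.assert_allclose(out.states, ss.states)

    def test_variance_adds(self):
        """Interior-supported input: output variance = input variance +
        sigma^2 within 3 standard errors at n=1e5."""
        rng = np.random.default_rng(8)
        x = rng.poisson(200.0, size=(100_000, 1)).astype(float)
        ss = cn.SampleSet(x)
        sigma = 5.0
        out = cn.shift_samples(ss, cn.ExtrinsicNoiseSpec(cov=sigma), seed=1)
        v_in = x.var()
        v_out = out.states.var()
        se = v_out * np.sqrt(2 / len(x))  # rough SE of a variance
        assert abs(v_out - (v_in + sigma**2)) < 3 * se

    def test_histogram_matches_grid_convolution(self, toggle_set1):
        """Two routes to the same convolution: shifting exact samples vs
        convolving the histogram."""
        _, space, dist = toggle_set1
        rng = np.random.default_rng(17)
        n = 100_000
        samples = cn.SampleSet(dist.sample_states(n, rng))
        spec = cn.ExtrinsicNoiseSpec(cov=1.0)
        shifted = cn.shift_samples(samples, spec, seed=3, round_to_lattice=True)
        grid_route = cn.convolve_grid(dist, spec)
        assert cn.ssd(shifted, grid_route, space=space) <= 0.002

    def test_background_points_appended(self, toggle_set1):
        _, space, dist = toggle_set1
        ss = cn.SampleSet(np.zeros((900, 2), dtype=int))
        out = cn.shift_samples(
            ss,
            cn.ExtrinsicNoiseSpec(cov=1.0, background_weight=0.1),
            seed=0,
            space=space,
        )
        assert len(out) == 1000  # 900 * 0.1/0.9 = 100 extra


class TestGammaMixing:
    @pytest.mark.parametrize(
        "alpha, theta, mean, var", [(20.0, 1.0, 20.0, 40.0), (10.0, 2.0, 20.0, 60.0)]
    )
    def test_moments(self, alpha, theta, mean, var):
        dist = cn.gamma_mixed_birth_death(alpha, theta, 200)
        assert dist.mean()[0] == pytest.approx(mean, abs=1e-6)
        assert dist.std()[0] ** 2 == pytest.approx(var, abs=1e-4)

    def test_matches_numerical_quadrature(self):
        """Closed form vs direct integration of Poisson(y) against the
        Gamma(alpha, theta) mixing density."""
        alpha, theta = 20.0, 1.0
        dist = cn.gamma_mixed_birth_death(alpha, theta, 60)
        ref = np.empty(61)
        for n in range(61):
            ref[n] = quad(
                lambda y, n=n: np.exp(
                    -y + n * np.log(y) - np.sum(np.log(np.arange(1, n + 1)))
                )
                * gamma_dist.pdf(y, alpha, scale=theta),
                0,
                np.inf,
                limit=500,
                epsabs=1e-13,
                epsrel=1e-12,
            )[0]
        ref /= ref.sum()
        np.testing.assert_allclose(dist.mass, ref, atol=1e-8)

    def test_degenerate_mixing_limit_is_poisson(self):
        lam = 20.0
        theta = 0.01
        dist = cn.gamma_mixed_birth_death(lam / theta, theta, 120)
        po = cn.poisson_constitutive(lam, 1.0, 120)
        assert float(np.sum((dist.mass - po.mass) ** 2)) < 1e-4


class TestSigmaFit:
    def test_recovers_known_sigma(self):
        po = cn.poisson_constitutive(20.0, 1.0, 120)
        target = cn.convolve_grid(po, cn.ExtrinsicNoiseSpec(cov=3.0))
        fit = cn.fit_extrinsic_sigma(po, target)
        assert fit.sigma == pytest.approx(3.0, abs=0.05)

    @pytest.mark.parametrize(
        "alpha, theta, expected", [(20.0, 1.0, 4.4), (10.0, 2.0, 6.1)]
    )
    def test_gamma_mixed_targets(self, alpha, theta, expected):
        """Best Gaussian-convolution fit (with mean shift) to the
        gamma-mixed distribution lands near the expected widths."""
        po = cn.poisson_constitutive(20.0, 1.0, 120)
        target = cn.gamma_mixed_birth_death(alpha, theta, 120)
        fit = cn.fit_extrinsic_sigma(po, target, fit_shift=True)
        assert fit.sigma == pytest.approx(expected, rel=0.15)
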