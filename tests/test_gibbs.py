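"""Modified Gibbs sampler: conditionals, rotated axes, mixing, diagnostics."""

import math

import numpy as np
import pytest
from scipy.stats import poisson

import cmenoise as cn
from cmenoise.gibbs import _rounded_line
from cmenoise.network import ModelError


class TestConditionalLine:
    def test_birth_death_axis_line_is_exact(self):
        """Detailed balance is exact in 1-D: the line conditional equals
        the closed-form steady state."""
        network, space = cn.make_birth_death(20.0, 1.0, 60)
        line = cn.axis_line(space, np.array([0]), 0)
        p = cn.conditional_line_distribution(network, np.array([0]), line)
        ref = cn.poisson_constitutive(20.0, 1.0, 60).mass
        np.testing.assert_allclose(p, ref, atol=1e-12)

    @pytest.mark.parametrize("v", [0, 2, 5])
    def test_toggle_u_conditional_is_poisson(self, toggle_set1, v):
        """Fixed v: U has constant synthesis r_u/(1+v^2) and linear
        degradation, so its conditional is Poisson with that mean."""
        network, space, _ = toggle_set1
        anchor = np.array([3, v])
        line = cn.axis_line(space, anchor, 0)
        p = cn.conditional_line_distribution(network, anchor, line)
        lam = 10.0 / (1 + v**2)
        ref = poisson.pmf(np.arange(61), lam)
        ref /= ref.sum()
        np.testing.assert_allclose(p, ref, atol=1e-12)

    def test_diagonal_line_symmetry_in_symmetric_toggle(self, toggle_symmetric):
        """u<->v symmetry: the conditional along the diagonal through the
        origin is invariant under swapping the two coordinates."""
        network, space, _ = toggle_symmetric
        anchor = np.array([0, 0])
        n = space.upper[0] + 1
        diag = np.column_stack([np.arange(n), np.arange(n)])
        p = cn.conditional_line_distribution(network, anchor, diag)
        swapped = cn.conditional_line_distribution(network, anchor, diag[:, ::-1])
        np.testing.assert_allclose(p, swapped, atol=1e-12)

    def test_anchor_must_be_on_line(self, toggle_set1):
        network, space, _ = toggle_set1
        line = cn.axis_line(space, np.array([0, 0]), 0)
        with pytest.raises(ModelError, match="anchor"):
            cn.conditional_line_distribution(network, np.array([5, 5]), line)

    def test_zero_synthesis_terminates_line(self):
        """Beyond a state where both step channels vanish, the line
        carries no mass."""
        network = cn.ReactionNetwork(
            ["n"],
            [
                cn.Reaction("synth", "k * max(0, 3 - n)", change=np.array([1])),
                cn.Reaction("deg", "n * 1.0", change=np.array([-1])),
            ],
            {"k": 5.0},
        )
        space = cn.StateSpace([10])
        line = cn.axis_line(space, np.array([0]), 0)
        p = cn.conditional_line_distribution(network, np.array([0]), line)
        assert p[:4].sum() == pytest.approx(1.0)
        # synthesis is zero from n=3 on: no mass can sit above n=3
        np.testing.assert_allclose(p[4:], 0.0)


class TestRotatedAxes:
    def test_zero_slope_gives_original_axes(self, toggle_set1):
        _, space, _ = toggle_set1
        anchor = np.array([7, 11])
        line1 = _rounded_line(space, anchor, free=0, dep=1, slope=0.0)
        np.testing.assert_array_equal(line1, cn.axis_line(space, anchor, 0))

    def test_axes_contain_anchor_and_only_integers(self, toggle_set1):
        _, space, _ = toggle_set1
        rng = np.random.default_rng(3)
        for _ in range(50):
            anchor = rng.integers(0, 61, size=2)
            axes = cn.draw_rotated_axes(anchor, space, rng)
            for line in axes.lines:
                assert line.dtype.kind == "i"
                assert np.any(np.all(line == anchor, axis=1))
                assert np.all((line >= 0) & (line <= space.upper))

    def test_perpendicular_slopes(self, toggle_set1):
        _, space, _ = toggle_set1
        anchor = np.array([30, 30])
        rng = np.random.default_rng(12)
        axes = cn.draw_rotated_axes(anchor, space, rng)
        m = axes.slope
        if math.isfinite(m) and m != 0:
            line2 = axes.lines[1]
            # consecutive second-axis points follow slope -1/m in (u, v)
            du = np.diff(line2[:, 0]).astype(float)
            dv = np.diff(line2[:, 1]).astype(float)
            fitted = np.polyfit(dv.cumsum(), du.cumsum(), 1)[0]
            assert fitted == pytest.approx(-m, abs=0.6)

    def test_deterministic_under_seed(self, toggle_set1):
        _, space, _ = toggle_set1
        anchor = np.array([5, 9])
        a1 = cn.draw_rotated_axes(anchor, space, np.random.default_rng(77))
        a2 = cn.draw_rotated_axes(anchor, space, np.random.default_rng(77))
        assert a1.slope == a2.slope
        for l1, l2 in zip(a1.lines, a2.lines):
            np.testing.assert_array_equal(l1, l2)


class TestSampler:
    def test_seed_determinism_and_length(self, toggle_set1):
        network, space, _ = toggle_set1
        s1 = cn.mgs_sample(network, space, 200, burn_in=50, seed=123)
        s2 = cn.mgs_sample(network, space, 200, burn_in=50, seed=123)
        np.testing.assert_array_equal(s1.states, s2.states)
        assert len(s1) == 200
        assert np.all(s1.states >= 0) and np.all(s1.states <= space.upper)

    def test_out_of_bounds_init_rejected(self, toggle_set1):
        network, space, _ = toggle_set1
        with pytest.raises(ModelError, match="outside"):
            cn.mgs_sample(network, space, 10, init=np.array([100, 0]))

    def test_sample_moments_converge_to_direct(self, toggle_set1):
        """Sample means approach the exact means at a rate consistent
        with 1/sqrt(n) (allowing for the sampler's approximation floor)."""
        network, space, dist = toggle_set1
        exact = dist.mean()
        errs = []
        for n in (1000, 4000, 16000):
            ss = cn.mgs_sample(network, space, n, burn_in=500, seed=9)
            errs.append(np.abs(ss.mean() - exact).sum())
        # not strictly monotone (stochastic + bias floor), but bounded
        assert errs[-1] < 4.0
        assert all(e < 6.0 for e in errs)

    def test_mode_balance_with_rotation(self, toggle_symmetric):
        """Rotation-enabled MGS splits time evenly between the two modes
        of the symmetric toggle."""
        network, space, _ = toggle_symmetric
        ss = cn.mgs_sample(network, space, 20000, burn_in=1000, seed=21)
        u, v = ss.states[:, 0], ss.states[:, 1]
        frac = (u > v).mean() + 0.5 * (u == v).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_axis_aligned_switches_modes_far_less(self, toggle_symmetric):
        """The qualitative contrast behind the rotation: axis-aligned
        Gibbs crosses between modes much more rarely than rotated MGS on
        the same budget."""
        network, space, _ = toggle_symmetric
        fp = cn.deterministic_fixed_points(network, space)[0]

        def switch_count(rotate):
            ss = cn.mgs_sample(
                network, space, 5000, burn_in=200, seed=5, rotate=rotate, init=fp
            )
            lab = np.sign(ss.states[:, 0] - ss.states[:, 1])
            lab = lab[lab != 0]
            return int((np.diff(lab) != 0).sum())

        rotated = switch_count(True)
        axis = switch_count(False)
        assert axis < 0.2 * rotated

    def test_mode_weights_pool_chains(self, toggle_set1):
        network, space, _ = toggle_set1
        fps = cn.deterministic_fixed_points(network, space)
        assert len(fps) == 2
        ss = cn.mgs_sample(
            network,
            space,
            1000,
            burn_in=100,
            seed=4,
            mode_weights=[(0.7, fps[0]), (0.3, fps[1])],
        )
        labels = ss.metadata["mode_labels"]
        assert len(ss) == 1000
        assert (labels == 0).sum() == 700
        assert (labels == 1).sum() == 300


class TestStationarity:
    def test_one_cycle_preserves_product_form_distribution(self, product_birth_death):
        """Where the per-species detailed-balance ratio is exact (two
        independent birth-death species), one rotated MGS cycle started
        from the exact distribution leaves the marginals statistically
        unchanged (chi-square, n=50,000)."""
        from scipy.stats import chisquare

        network, space, dist = product_birth_death
        rng = np.random.default_rng(42)
        n = 50_000
        starts = dist.sample_states(n, rng)
        out = np.empty_like(starts)
        for k in range(n):
            out[k] = cn.mgs_cycle(network, space, starts[k], rng, rotate=True)
        for i in range(2):
            exp = dist.marginal(i) * n
            obs = np.bincount(out[:, i], minlength=space.shape[i]).astype(float)
            last = np.nonzero(exp >= 5)[0].max()
            obs2 = np.append(obs[:last], obs[last:].sum())
            exp2 = np.append(exp[:last], exp[last:].sum())
            _, p = chisquare(obs2, exp2 * obs2.sum() / exp2.sum())
            assert p > 0.01


class TestDetailedBalanceDiagnostic:
    def test_exact_in_one_dimension(self):
        network, space = cn.make_birth_death(20.0, 1.0, 60)
        dist = cn.solve_steady_state(cn.build_generator(network, space), space)
        err = cn.detailed_balance_error(network, dist)
        assert err["n"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_toggle_has_equal_errors(self, toggle_symmetric):
        network, _, dist = toggle_symmetric
        err = cn.detailed_balance_error(network, dist)
        assert err["u"] == pytest.approx(err["v"], abs=1e-9)

    def test_species_without_channels_absent(self):
        network = cn.ReactionNetwork(
            ["a", "b"],
            [
                cn.Reaction("synth_a", "2.0", change=np.array([1, 0])),
                cn.Reaction("deg_a", "a * 1.0", change=np.array([-1, 0])),
            ],
            {},
        )
        space = cn.StateSpace([20, 0])  # b frozen: chain stays connected
        dist = cn.solve_steady_state(cn.build_generator(network, space), space)
        err = cn.detailed_balance_error(network, dist)
        assert "b" not in err


def test_deterministic_fixed_points_of_toggle(toggle_set1):
    """The two stable states sit near (r_u, ~0) and (~0, r_v)."""
    network, space, _ = toggle_set1
    fps = cn.deterministic_fixed_points(network, space)
    assert len(fps) == 2
    assert fps[0][0] >= 9 and fps[0][1] <= 1
    assert fps[1][0] <= 1 and fps[1][1] >= 8
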