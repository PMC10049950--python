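"""MBAR solver, PMF estimation, uncertainties, convergence, occurrence."""

import numpy as np
import pytest

from fabstab.constants import KB, T_DEFAULT, kt
from fabstab.reweighting import (UmbrellaWindow, convergence_split,
                                 estimate_pmf, make_window_ladder,
                                 pmf_from_weights, pmf_uncertainty,
                                 reduced_bias_matrix, reweighted_occurrence,
                                 solve_mbar, solve_windows)
from fabstab.synthetic import (ToyPotential, boltzmann_pmf,
                               simulate_umbrella_ladder,
                               simulate_umbrella_window)


def _window(center, samples, spring=1000.0, index=0):
    return UmbrellaWindow(index=index, center=center, spring=spring,
                          temperature=T_DEFAULT, samples=np.asarray(samples))


def sc_iteration_oracle(u, n_k, f0, n_iter=30_000, tol=1e-12):
    """Plain self-consistent fixed-point iteration, no Newton, any start."""
    from scipy.special import logsumexp
    f = np.asarray(f0, dtype=float)
    log_nk = np.log(n_k)
    for _ in range(n_iter):
        log_c = logsumexp(log_nk[:, None] + f[:, None] - u, axis=0)
        f_new = -logsumexp(-u - log_c[None, :], axis=1)
        f_new -= f_new[0]
        if np.max(np.abs(f_new - f)) < tol:
            return f_new
        f = f_new
    return f


class TestWindowLadder:
    def test_default_ladder_has_29_centers(self):
        c = make_window_ladder()
        assert len(c) == 29
        assert c[0] == 1.7 and c[-1] == 4.0
        assert np.all(np.diff(c) > 0)
        # spacing pattern: 0.1 below 2.0, 0.05 between 2.0 and 2.5, 0.1 above
        d = np.diff(c)
        assert np.allclose(d[(c[:-1] >= 2.0) & (c[1:] <= 2.5)], 0.05)
        assert np.allclose(d[c[1:] <= 2.0], 0.1)
        assert np.allclose(d[c[:-1] >= 2.5], 0.1)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            make_window_ladder(lo=2.0, mid_lo=2.0, mid_hi=2.5, hi=4.0)

    def test_single_segment(self):
        c = make_window_ladder(lo=0.0, mid_lo=0.5, mid_hi=0.75, hi=1.0,
                               coarse_step=0.5, fine_step=0.25)
        assert np.allclose(c, [0.0, 0.5, 0.75, 1.0])

    def test_non_commensurate_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            c = make_window_ladder(lo=0.0, mid_lo=0.35, mid_hi=0.7, hi=1.0,
                                   coarse_step=0.2, fine_step=0.35)
        assert c[-1] == 1.0 and np.all(np.diff(c) > 0)


class TestReducedBias:
    def test_zero_at_center_and_hand_arithmetic(self):
        w = [_window(2.0, [2.0, 2.1], spring=1000.0)]
        u, x, n_k = reduced_bias_matrix(w)
        assert u[0, 0] == 0.0
        # 1000 * 0.1^2 / (2 * kB * 310) = 1.9399...
        expect = 1000.0 * 0.01 / (2 * KB * 310.0)
        assert u[0, 1] == pytest.approx(expect, rel=1e-9)
        assert expect == pytest.approx(1.94, abs=0.005)

    def test_doubling_spring_doubles_entries(self):
        w1 = [_window(2.0, [2.05, 2.2], spring=500.0)]
        w2 = [_window(2.0, [2.05, 2.2], spring=1000.0)]
        u1 = reduced_bias_matrix(w1)[0]
        u2 = reduced_bias_matrix(w2)[0]
        assert np.allclose(u2, 2 * u1)

    def test_mixed_temperatures_rejected(self):
        w = [_window(2.0, [2.0]),
             UmbrellaWindow(1, 2.1, 1000.0, 300.0, np.array([2.1]))]
        with pytest.raises(ValueError, match="temperature"):
            reduced_bias_matrix(w)


class TestSolveMbar:
    def test_single_state_identity(self):
        u = np.zeros((1, 5))
        res = solve_mbar(u, [5])
        assert res.f[0] == 0.0
        assert np.allclose(res.weights, 0.2)
        assert res.converged

    def test_identical_rows_give_equal_f(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(0, 3, 50)
        u = np.vstack([row, row])
        res = solve_mbar(u, [25, 25])
        assert res.f[1] == pytest.approx(0.0, abs=1e-9)

    def test_weights_normalized_nonnegative(self, morse):
        wins = simulate_umbrella_ladder(morse, [1.9, 2.0, 2.1], n_steps=3000,
                                        seed=0, stride=5)
        res, _ = solve_windows(wins)
        assert np.all(res.weights >= 0)
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-10)

    def test_gaussian_partition_ratio(self, flat):
        """Two springs on a flat landscape: delta f = -ln(Z1/Z0)
        = 0.5 ln(kappa1/kappa0) from the Gaussian integrals."""
        kbt = kt()
        w0 = simulate_umbrella_window(flat, 2.0, spring=500.0, n_steps=100_000,
                                      stride=10, seed=21)
        w1 = simulate_umbrella_window(flat, 2.0, spring=2000.0, n_steps=100_000,
                                      stride=10, seed=22)
        w1.index = 1
        res, _ = solve_windows([w0, w1])
        expect = 0.5 * np.log(2000.0 / 500.0)
        n_eff = w0.n_samples / 5
        se = np.sqrt(2.0 / n_eff)
        assert abs(res.f[1] - expect) < 3 * se

    def test_agrees_with_independent_fixed_point_oracle(self, morse):
        wins = simulate_umbrella_ladder(morse, [1.9, 2.0, 2.1, 2.2],
                                        n_steps=4000, seed=3, stride=5)
        u, x, n_k = reduced_bias_matrix(wins)
        res = solve_mbar(u, n_k)
        rng = np.random.default_rng(5)
        oracle = sc_iteration_oracle(u, n_k, rng.normal(0, 2, len(wins)))
        assert np.max(np.abs(res.f - oracle)) < 1e-6

    def test_invariant_to_sample_ordering_and_window_permutation(self, morse):
        wins = simulate_umbrella_ladder(morse, [1.9, 2.0, 2.1], n_steps=3000,
                                        seed=1, stride=5)
        u, x, n_k = reduced_bias_matrix(wins)
        res = solve_mbar(u, n_k)
        # permute pooled samples consistently
        rng = np.random.default_rng(0)
        perm = rng.permutation(u.shape[1])
        res_p = solve_mbar(u[:, perm], n_k)
        assert np.allclose(res.f, res_p.f, atol=1e-8)
        # relabeling windows permutes f; free-energy differences must agree
        wperm = [2, 0, 1]
        res_w = solve_mbar(u[wperm], np.asarray(n_k)[wperm])
        back = [res_w.f[wperm.index(k)] - res_w.f[wperm.index(0)]
                for k in range(3)]
        assert np.allclose(res.f, back, atol=1e-8)

    def test_nonconvergence_flagged(self, morse):
        wins = simulate_umbrella_ladder(morse, [1.9, 2.3], n_steps=2000,
                                        seed=0, stride=5)
        u, x, n_k = reduced_bias_matrix(wins)
        res = solve_mbar(u, n_k, max_iter=1)
        assert not res.converged
        assert res.residual > 1e-8


class TestPMF:
    def test_uniform_weights_uniform_samples_flat(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 100_000)
        w = np.full(x.size, 1 / x.size)
        pmf = pmf_from_weights(x, w, np.linspace(0, 1, 11))
        # the profile spread is bounded by the multinomial bin fluctuation
        # (max minus min over 10 bins, each ~ kT/sqrt(n_bin))
        sigma = kt() / np.sqrt(10_000)
        assert np.nanmax(np.abs(pmf.free_energy)) < 6 * sigma

    def test_weight_scaling_gauge_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 1000)
        w = rng.uniform(0, 1, 1000)
        edges = np.linspace(0, 1, 6)
        a = pmf_from_weights(x, w, edges)
        b = pmf_from_weights(x, 7.3 * w, edges)
        assert np.allclose(a.free_energy, b.free_energy, equal_nan=True)

    def test_harmonic_profile_matches_quadrature(self):
        pot = ToyPotential("harmonic", depth=2.0, width=2.0, r0=2.0,
                           domain=(1.0, 3.0))
        wins = simulate_umbrella_ladder(pot, np.arange(1.4, 2.7, 0.1),
                                        n_steps=20_000, stride=10, seed=7)
        pmf = estimate_pmf(wins, edges=np.arange(1.4, 2.65, 0.05))
        exact = boltzmann_pmf(pot, pmf.edges)
        err = np.abs(pmf.free_energy - exact)[pmf.occupied]
        assert np.max(err) < 0.3 * kt()

    def test_empty_bins_masked_and_all_empty_rejected(self):
        x = np.array([0.1, 0.12])
        w = np.array([0.5, 0.5])
        pmf = pmf_from_weights(x, w, np.array([0.0, 0.2, 0.4]))
        assert pmf.occupied[0] and not pmf.occupied[1]
        assert np.isnan(pmf.free_energy[1])
        with pytest.raises(ValueError):
            pmf_from_weights(x, w, np.array([1.0, 2.0]))


@pytest.fixture(scope="module")
def small_windows(morse):
    return simulate_umbrella_ladder(morse, [1.9, 2.0, 2.1, 2.2, 2.3],
                                    n_steps=3000, seed=11, stride=10)


class TestPmfUncertainty:
    def test_deterministic_given_seed(self, small_windows):
        edges = np.arange(1.8, 2.45, 0.05)
        a = pmf_uncertainty(small_windows, edges, n_boot=20, seed=4)
        b = pmf_uncertainty(small_windows, edges, n_boot=20, seed=4)
        assert np.array_equal(a, b, equal_nan=True)

    def test_stable_between_20_and_200_replicates(self, small_windows):
        edges = np.arange(1.8, 2.45, 0.05)
        s20 = pmf_uncertainty(small_windows, edges, n_boot=20, seed=1)
        s200 = pmf_uncertainty(small_windows, edges, n_boot=200, seed=1)
        good = ~np.isnan(s20) & ~np.isnan(s200) & (s200 > 0)
        ratio = s20[good] / s200[good]
        assert np.all((ratio > 0.5) & (ratio < 2.0))

    def test_minimum_replicates_enforced(self, small_windows):
        with pytest.raises(ValueError):
            pmf_uncertainty(small_windows, np.arange(1.8, 2.4, 0.05), n_boot=5)


class TestConvergenceSplit:
    def test_duplicated_halves_give_zero_deviation(self):
        rng = np.random.default_rng(0)
        wins = []
        for k, c in enumerate([1.9, 2.0, 2.1]):
            half = c + rng.normal(0, 0.05, 200)
            wins.append(_window(c, np.concatenate([half, half]), index=k))
        _, _, dev = convergence_split(wins, edges=np.arange(1.7, 2.35, 0.05))
        assert dev == 0.0

    def test_single_sample_windows_rejected(self):
        with pytest.raises(ValueError):
            convergence_split([_window(2.0, [2.0])])

    def test_converged_toy_below_one_kt(self, morse):
        wins = simulate_umbrella_ladder(morse, np.arange(1.8, 3.01, 0.1),
                                        n_steps=60_000, stride=30, seed=2)
        # compare over the window-covered range; bins beyond the last center
        # are tail-sampled and not part of the converged profile
        _, _, dev = convergence_split(wins, edges=np.arange(1.75, 3.01, 0.05))
        assert dev < kt()


class TestReweightedOccurrence:
    def test_always_present_is_one(self):
        w = np.array([0.2, 0.3, 0.5])
        assert reweighted_occurrence(np.ones(3, bool), w) == 1.0

    def test_uniform_weights_half_present(self):
        present = np.array([True, False] * 50)
        assert reweighted_occurrence(present, np.ones(100) / 100) == 0.5

    def test_identical_biases_reduce_to_plain_mean(self):
        """When every frame carries the same bias energy in every window the
        weights are uniform and the occurrence is the plain average."""
        rng = np.random.default_rng(0)
        u = np.full((2, 400), 1.94)
        res = solve_mbar(u, [200, 200])
        assert np.allclose(res.weights, 1 / 400)
        present = rng.random(400) < 0.37
        assert reweighted_occurrence(present, res) == \
            pytest.approx(present.mean(), abs=1e-12)

    def test_zero_weight_mask_rejected(self):
        with pytest.raises(ValueError):
            reweighted_occurrence(np.ones(3, bool), np.ones(3) / 3,
                                  np.zeros(3, bool))

    def test_biased_run_matches_unbiased_average(self):
        """Reweighted occupancy of cv < 2.5 on a shallow well equals the
        unbiased long-run average (and the exact Boltzmann value)."""
        pot = ToyPotential("morse_well", depth=2.0, width=6.0, r0=2.0,
                           domain=(1.6, 3.2))
        wins = simulate_umbrella_ladder(pot, np.arange(1.7, 3.11, 0.1),
                                        n_steps=120_000, stride=60, seed=13)
        res, x = solve_windows(wins)
        occ = reweighted_occurrence(x < 2.5, res)
        free = simulate_umbrella_window(pot, center=2.4, spring=1e-6,
                                        n_steps=1_000_000, stride=20, seed=14)
        assert abs(occ - np.mean(free.samples < 2.5)) < 0.05
        from fabstab.synthetic import boltzmann_density
        grid, dens = boltzmann_density(pot)
        exact = np.trapezoid(dens[grid < 2.5], grid[grid < 2.5])
        assert abs(occ - exact) < 0.05
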