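"""Folding kinetics: exponential fits, chevrons, half-life, double jump."""

import numpy as np
import pytest

from knottrp import (
    fit_chevron_limb,
    fit_double_jump,
    fit_exponential,
    half_life_in_water,
    kinetic_partition_fractions,
    simulate_chevron,
    simulate_double_jump,
    simulate_trace,
)
from knottrp.kinetics import KineticsError, SECONDS_PER_YEAR, chevron_rate


class TestExponentialFit:
    def test_noiseless_single_exponential_exact(self):
        t, y = simulate_trace([1.0], [1.0], 0.2, 6.0, n_points=300)
        fit = fit_exponential(t, y, n_phases=1, dead_time=0.0)
        assert fit.rates[0] == pytest.approx(1.0, abs=1e-9)
        assert fit.amplitudes[0] == pytest.approx(1.0, abs=1e-9)
        assert fit.offset == pytest.approx(0.2, abs=1e-9)

    def test_double_exponential_recovery_at_one_percent_noise(self):
        # Fast/slow refolding phases of an interrupted-unfolding experiment.
        t, y = simulate_trace([0.75, 0.25], [212.0, 18.0], 0.1, 0.4,
                              n_points=4000, noise_sd=0.01, seed=2)
        fit = fit_exponential(t, y, n_phases=2, dead_time=0.0)
        assert fit.rates[0] == pytest.approx(212.0, rel=0.02)
        assert fit.rates[1] == pytest.approx(18.0, rel=0.02)

    def test_amplitude_fractions_from_75_25_mixture(self):
        t, y = simulate_trace([0.75, 0.25], [212.0, 18.0], 0.0, 0.4,
                              n_points=4000, noise_sd=0.005, seed=3)
        fit = fit_exponential(t, y, n_phases=2, dead_time=0.0)
        f = fit.amplitude_fractions
        assert f[0] == pytest.approx(0.75, abs=0.03)
        assert f[1] == pytest.approx(0.25, abs=0.03)

    def test_dead_time_points_excluded(self):
        t = np.linspace(0, 1, 200)
        y = np.exp(-3 * t)
        y[t < 0.002] = 99.0  # corrupt the dead-time points
        fit = fit_exponential(t, y, n_phases=1, dead_time=0.002)
        assert fit.rates[0] == pytest.approx(3.0, rel=1e-6)

    def test_time_rescaling_equivariance(self):
        t, y = simulate_trace([1.0], [5.0], 0.0, 2.0, n_points=500,
                              noise_sd=0.002, seed=4)
        f1 = fit_exponential(t, y, dead_time=0.0)
        f2 = fit_exponential(10.0 * t, y, dead_time=0.0)
        assert f2.rates[0] == pytest.approx(f1.rates[0] / 10.0, rel=1e-6)
        assert f2.amplitudes[0] == pytest.approx(f1.amplitudes[0], rel=1e-6)


class TestChevron:
    def test_exact_line_recovered(self):
        den = np.array([6.25, 6.5, 6.75, 7.0, 7.25])
        k = np.exp(-20.0 + 1.2 * den)
        fit = fit_chevron_limb(den, k, "unfolding")
        assert fit.ln_k_water == pytest.approx(-20.0, abs=1e-9)
        assert fit.m_k == pytest.approx(1.2, abs=1e-9)

    def test_window_excludes_rollover_points(self):
        den, k = simulate_chevron(np.linspace(0.7, 5.5, 20), ln_ku0=-25, m_ku=2.8,
                                  ln_kf0=14.0, m_kf=-2.6, ln_k_pre=np.log(200.0))
        fit_all = fit_chevron_limb(den, k, "refolding")
        fit_win = fit_chevron_limb(den, k, "refolding", window=(4.2, 5.5))
        # With the rollover region included, the line fit degrades.
        assert fit_win.r_squared > 0.999
        assert fit_all.r_squared < fit_win.r_squared
        assert fit_win.m_k == pytest.approx(-2.6, abs=0.1)

    def test_curvature_diagnostic_flags_rollover(self):
        den, k = simulate_chevron(np.linspace(0.7, 5.5, 24), ln_ku0=-25, m_ku=2.8,
                                  ln_kf0=14.0, m_kf=-2.6, ln_k_pre=np.log(200.0))
        fit_all = fit_chevron_limb(den, k, "refolding")
        fit_win = fit_chevron_limb(den, k, "refolding", window=(4.2, 5.5))
        assert fit_all.curvature_p < 0.05 or fit_all.r_squared < 0.99
        assert fit_win.r_squared > 0.999

    def test_fewer_than_three_points_raises(self):
        with pytest.raises(KineticsError):
            fit_chevron_limb([6.0, 6.5], [1.0, 2.0])


class TestHalfLife:
    def test_century_scale_half_life(self):
        """k_U(H2O) = 2.2e-10 s^-1 corresponds to a ~100-year half-life."""
        fit = fit_chevron_limb(np.array([6.0, 6.5, 7.0]),
                               np.exp(np.log(2.2e-10) + 1.2 * np.array([6.0, 6.5, 7.0])),
                               "unfolding")
        k_w, years = half_life_in_water(fit)
        assert k_w == pytest.approx(2.2e-10, rel=1e-6)
        assert years == pytest.approx(99.86, abs=0.5)

    def test_ln2_rate_gives_one_second(self):
        fit = fit_chevron_limb(np.array([1.0, 2.0, 3.0]),
                               np.full(3, np.log(2.0)), "unfolding")
        _, years = half_life_in_water(fit)
        assert years * SECONDS_PER_YEAR == pytest.approx(1.0, rel=1e-9)

    def test_doubling_rate_halves_half_life(self):
        den = np.array([1.0, 2.0, 3.0])
        f1 = fit_chevron_limb(den, np.full(3, 1e-8), "unfolding")
        f2 = fit_chevron_limb(den, np.full(3, 2e-8), "unfolding")
        assert half_life_in_water(f1)[1] == pytest.approx(
            2.0 * half_life_in_water(f2)[1], rel=1e-9)

    def test_refolding_limb_rejected(self):
        fit = fit_chevron_limb(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]),
                               "refolding")
        with pytest.raises(KineticsError):
            half_life_in_water(fit)


class TestPartition:
    def test_equal_rates_split_evenly(self):
        assert kinetic_partition_fractions(1.0, 1.0) == (0.5, 0.5)

    def test_observed_rate_pair_gives_92_8(self):
        f1, f2 = kinetic_partition_fractions(212.0, 18.0)
        assert f1 == pytest.approx(0.9217, abs=1e-4)
        assert f2 == pytest.approx(0.0783, abs=1e-4)

    def test_fractions_always_sum_to_one(self, rng):
        for _ in range(20):
            k1, k2 = rng.uniform(1e-3, 1e3, 2)
            f1, f2 = kinetic_partition_fractions(k1, k2)
            assert f1 + f2 == pytest.approx(1.0, abs=1e-12)


class TestDoubleJump:
    def test_decay_rate_recovered_at_two_percent_noise(self):
        t, k = simulate_double_jump(np.linspace(0.05, 15, 14), k0=212.0,
                                    k_inf=37.0, lam=0.25, noise_frac=0.02, seed=5)
        fit = fit_double_jump(t, k)
        assert fit.decay_rate == pytest.approx(0.25, rel=0.10)

    def test_flat_series_gives_near_zero_decay(self):
        t, k = simulate_double_jump(np.linspace(0.1, 10, 10), k0=50.0,
                                    k_inf=50.0, lam=0.0, noise_frac=0.01, seed=6)
        fit = fit_double_jump(t, k)
        assert fit.decay_rate < 0.05 or fit.decay_rate_ci[0] <= 0.0

    def test_both_phases_share_decay_rate_within_ci(self):
        t_grid = np.linspace(0.05, 15, 14)
        t1, k1 = simulate_double_jump(t_grid, 212.0, 37.0, 0.25,
                                      noise_frac=0.02, seed=7)
        t2, k2 = simulate_double_jump(t_grid, 18.0, 5.5, 0.25,
                                      noise_frac=0.02, seed=8)
        f1, f2 = fit_double_jump(t1, k1), fit_double_jump(t2, k2)
        assert f1.decay_rate_ci[0] <= f2.decay_rate <= f1.decay_rate_ci[1]


class TestPhaseAssignment:
    def test_phases_tracked_by_log_rate_continuity(self):
        from knottrp import assign_phases

        assert assign_phases((200.0, 20.0), (15.0, 180.0)) == (180.0, 15.0)
        # Order preserved when already aligned.
        assert assign_phases((200.0, 20.0), (150.0, 30.0)) == (150.0, 30.0)

    def test_mismatched_phase_counts_raise(self):
        from knottrp import assign_phases

        with pytest.raises(KineticsError):
            assign_phases((1.0, 2.0), (1.0,))


class TestSimulateAndConsistency:
    def test_zero_noise_chevron_is_exact(self):
        den = np.linspace(1, 7, 12)
        _, k = simulate_chevron(den, -20, 2.0, 10, -2.0)
        assert np.abs(k - chevron_rate(den, -20, 2.0, 10, -2.0)).max() == 0.0

    def test_same_seed_identical(self):
        den = np.linspace(1, 7, 12)
        _, k1 = simulate_chevron(den, -20, 2.0, 10, -2.0, noise_frac=0.05, seed=1)
        _, k2 = simulate_chevron(den, -20, 2.0, 10, -2.0, noise_frac=0.05, seed=1)
        assert np.array_equal(k1, k2)

    def test_rollover_refolding_rate_plateaus_at_low_denaturant(self):
        """Sequential D->I->N scheme: below the switch concentration the
        denaturant-insensitive step is rate limiting."""
        den_low = np.linspace(0.5, 2.5, 9)
        _, k_low = simulate_chevron(den_low, ln_ku0=-30, m_ku=2.8, ln_kf0=14.0,
                                    m_kf=-2.6, ln_k_pre=np.log(200.0))
        assert k_low.max() / k_low.min() < 1.6
        den_hi = np.linspace(4.0, 5.5, 7)
        _, k_hi = simulate_chevron(den_hi, ln_ku0=-30, m_ku=2.8, ln_kf0=14.0,
                                   m_kf=-2.6, ln_k_pre=np.log(200.0))
        assert k_hi.max() / k_hi.min() > 5.0

    def test_kinetic_equals_equilibrium_thermodynamics_on_two_state_data(self):
        """Chevron limbs of a two-state simulation return m and ΔG within
        5% of the generating equilibrium values (noiseless)."""
        RT = 1.987e-3 * 298.15
        m_eq, dG_eq = 2.0, 10.0
        m_kf, m_ku = -0.65 * m_eq / RT, 0.35 * m_eq / RT
        ln_kf0 = 3.0
        ln_ku0 = ln_kf0 - dG_eq / RT
        den = np.linspace(0.2, 12.0, 60)
        _, k = simulate_chevron(den, ln_ku0, m_ku, ln_kf0, m_kf)
        d50 = dG_eq / m_eq
        fold = fit_chevron_limb(den, k, "refolding", window=(0.0, d50 - 2.0))
        unfold = fit_chevron_limb(den, k, "unfolding", window=(d50 + 2.0, 12.0))
        m_hat = RT * (unfold.m_k - fold.m_k)
        dG_hat = RT * (fold.ln_k_water - unfold.ln_k_water)
        assert m_hat == pytest.approx(m_eq, rel=0.05)
        assert dG_hat == pytest.approx(dG_eq, rel=0.05)
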