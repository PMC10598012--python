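"""Force spectroscopy: detection, elasticity, contour lengths, Bell-Evans."""

import numpy as np
import pytest

from knottrp import (
    ElasticityParams,
    ForceCurve,
    PullingSegment,
    bell_evans_density,
    bending_correction,
    compare_force_spectra,
    contour_length_transform,
    denoise_and_detect,
    fit_bell_evans,
    frc_extension,
    invert_frc,
    loading_rate,
    most_probable_force,
    qm_corrected_residue_length,
    simulate_pulling,
)
from knottrp.smfs import SmfsError, _frc_fraction, _stretch_factor, solve_frc_force

EP = ElasticityParams()


def sawtooth_curve(peak_force=80.0, noise_sd=5.0, seed=0, n=2000,
                   velocity=1600.0, k=100.0, peak_at=0.4):
    """Synthetic linear-rise sawtooth with one rupture and a flat baseline."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0, 200, n)
    F = np.zeros(n)
    ipk = int(peak_at * n)
    F[:ipk + 1] = np.linspace(0, peak_force, ipk + 1)
    F += rng.normal(0, noise_sd, n)
    return ForceCurve(x, F, velocity, k), ipk


class TestBendingCorrection:
    def test_direct_formula(self):
        c = ForceCurve([100.0, 50.0], [100.0, 0.0], 1600.0, 100.0)
        xc = bending_correction(c)
        assert xc[0] == pytest.approx(99.0)
        assert xc[1] == pytest.approx(50.0)  # zero force leaves x unchanged

    def test_linearity_in_force(self):
        x = np.linspace(0, 10, 20)
        F1, F2 = np.linspace(0, 50, 20), np.linspace(0, 30, 20)
        a = bending_correction(ForceCurve(x, F1 + F2, 1.0, 100.0))
        b = bending_correction(ForceCurve(x, F1, 1.0, 100.0))
        c = bending_correction(ForceCurve(x, F2, 1.0, 100.0))
        assert np.abs((x - a) - ((x - b) + (x - c))).max() < 1e-12


class TestDetection:
    def test_single_sawtooth_detected_within_three_points(self):
        hits = 0
        for seed in range(50):
            curve, ipk = sawtooth_curve(seed=seed)
            events = denoise_and_detect(curve)
            if len(events) == 1 and abs(events[0].index - ipk) <= 3:
                hits += 1
        assert hits == 50

    def test_pure_noise_rarely_triggers(self):
        clean = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            curve = ForceCurve(np.linspace(0, 100, 1500),
                               rng.normal(0, 5.0, 1500), 1600.0, 100.0)
            if len(denoise_and_detect(curve)) == 0:
                clean += 1
        assert clean >= 95

    def test_two_separated_ruptures_in_order(self):
        rng = np.random.default_rng(1)
        n = 3000
        x = np.linspace(0, 300, n)
        F = np.zeros(n)
        F[:800] = np.linspace(0, 90, 800)
        F[1200:2000] = np.linspace(20, 110, 800)
        F += rng.normal(0, 4.0, n)
        curve = ForceCurve(x, F, 1600.0, 100.0)
        events = denoise_and_detect(curve)
        assert len(events) == 2
        assert events[0].index < events[1].index
        assert events[0].force == pytest.approx(90, abs=15)
        assert events[1].force == pytest.approx(110, abs=15)


class TestLoadingRate:
    def test_linear_ramp_slope_exact(self):
        x = np.linspace(0, 100, 2000)
        v = 1000.0  # nm/s -> t = x/v; F = 10 pN/nm * x -> 1e4 pN/s
        curve = ForceCurve(x, 10.0 * x, v, 1e9)
        from knottrp.smfs import RuptureEvent

        ev = RuptureEvent(1000.0, 100.0, 1999)
        assert loading_rate(curve, ev) == pytest.approx(1e4, rel=1e-9)

    def test_window_parameter_honoured(self):
        # Slope changes 2x at the last 2 nm: a 2 nm window sees only that.
        x = np.linspace(0, 10, 1001)
        F = np.where(x < 8.0, 5.0 * x, 40.0 + 10.0 * (x - 8.0))
        curve = ForceCurve(x, F, 1.0, 1e9)
        from knottrp.smfs import RuptureEvent

        ev = RuptureEvent(60.0, 10.0, 1000)
        assert loading_rate(curve, ev, window_nm=2.0) == pytest.approx(10.0, rel=1e-6)
        assert loading_rate(curve, ev, window_nm=4.0) < 10.0

    def test_simulated_curve_slope_close_to_numeric_derivative(self):
        curve = simulate_pulling([PullingSegment(45.0, 0.4, 0.25)],
                                 initial_contour=70.0, seed=3)
        events = denoise_and_detect(curve)
        assert events
        ev = events[0]
        r = loading_rate(curve, ev)
        # Noise-free replica of the same ramp (noise is added after the
        # rupture draw, so the geometry is identical).
        clean = simulate_pulling([PullingSegment(45.0, 0.4, 0.25)],
                                 initial_contour=70.0, seed=3, noise_sd=0.0)
        t, F = clean.time, clean.force
        i0 = int(np.argmax(F[: ev.index + 5]))  # clean peak next to the event
        # Noise-free secant over the same 4 nm (16-step) pre-peak span.
        dnum = (F[i0] - F[i0 - 16]) / (t[i0] - t[i0 - 16])
        assert r == pytest.approx(dnum, rel=0.15)


class TestElasticity:
    def test_zero_force_zero_extension(self):
        assert frc_extension(0.0, 45.0, EP) == 0.0

    def test_strictly_monotone_over_grid(self):
        F = np.geomspace(0.1, 2000.0, 10_000)
        x = frc_extension(F, 45.0, EP)
        assert np.all(np.diff(x) > 0)

    def test_extension_approaches_contour_length(self):
        assert frc_extension(1e5, 45.0, EP) == pytest.approx(45.0, rel=1e-3)

    def test_intensive_form_independent_of_length(self):
        F = np.geomspace(0.5, 3000.0, 200)
        g1 = frc_extension(F, 45.0, EP) / 45.0
        g2 = frc_extension(F, 123.0, EP) / 123.0
        assert np.abs(g1 - g2).max() < 1e-12

    def test_numeric_inverse_round_trips(self):
        for L in (20.0, 45.0, 80.0):
            for x in (0.3 * L, 0.7 * L, 0.9 * L):
                F = solve_frc_force(x, L, EP)
                back = frc_extension(F, L, EP) * _stretch_factor(F, EP)
                assert back == pytest.approx(x, abs=1e-9)


class TestQMCorrection:
    def test_zero_force_residue_length(self):
        assert qm_corrected_residue_length(0.0, EP) == pytest.approx(0.36)

    def test_non_decreasing_in_force(self):
        F = np.linspace(0, 3000, 500)
        L = qm_corrected_residue_length(F, EP)
        assert np.all(np.diff(L) >= 0)
        assert L[-1] > L[0]

    def test_off_switch_reproduces_pure_frc_inversion(self):
        ep_off = ElasticityParams(qm_stretch_modulus=None)
        F = np.geomspace(15, 2000, 50)
        x = 45.0 * _frc_fraction(F, ep_off)
        assert np.abs(invert_frc(F, x, ep_off) - 45.0).max() < 1e-9


class TestContourLength:
    def test_single_segment_kde_peak_at_45(self):
        """A curve stretching one 45 nm contour gives its KDE peak there."""
        curve = simulate_pulling([], initial_contour=45.0, seed=4,
                                 f_detach=800.0)
        _, _, _, peaks = contour_length_transform(curve)
        assert abs(peaks[0] - 45.0) <= 1.0

    def test_two_segment_increment(self):
        curve = simulate_pulling([PullingSegment(40.0, 0.4, 0.25)],
                                 initial_contour=20.0, seed=5)
        _, _, _, peaks = contour_length_transform(curve)
        two = np.sort(peaks[:2])
        assert abs(two[0] - 20.0) <= 1.5
        assert abs((two[1] - two[0]) - 40.0) <= 1.5

    def test_high_force_asymptote_recovers_length(self):
        F = np.array([500.0])
        x = 45.0 * _frc_fraction(F, EP) * _stretch_factor(F, EP)
        assert invert_frc(F, x, EP)[0] == pytest.approx(45.0, rel=0.005)

    def test_expected_full_unfolding_increment_for_170_residues(self):
        # 170 residues x 0.36 nm/residue of freed contour length.
        assert 170 * EP.residue_length == pytest.approx(61.2)


class TestBellEvans:
    DX, KOFF0, KBT = 0.40, 0.25, 4.11

    def _sample(self, rate, n, seed):
        Fg = np.linspace(0.01, 300, 20_000)
        pdf = bell_evans_density(Fg, rate, self.DX, self.KOFF0, self.KBT)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        rng = np.random.default_rng(seed)
        return np.interp(rng.uniform(size=n), cdf, Fg)

    def test_parameters_recovered_from_be_samples(self):
        """Forces sampled at the rate giving F* = 83 pN: Δx within 10% per
        draw; k_off,0 unbiased (median within 10%, each within factor 2)."""
        rate = self.KOFF0 * self.KBT / self.DX * np.exp(83.0 * self.DX / self.KBT)
        dx_errs, k_ratio, fstar_err = [], [], []
        for seed in range(16):
            fit = fit_bell_evans(self._sample(rate, 1000, seed), rate)
            dx_errs.append(abs(fit.dx / self.DX - 1.0))
            k_ratio.append(fit.koff0 / self.KOFF0)
            fstar_err.append(abs(fit.most_probable_force - 83.0))
        assert max(dx_errs) < 0.10
        # k_off,0 is exponentially sensitive: unbiased but heavy-tailed.
        assert abs(np.median(k_ratio) - 1.0) < 0.25
        assert max(max(k_ratio), 1 / min(k_ratio)) < 2.0
        assert np.median(fstar_err) < 3.0

    def test_analytic_mode_matches_numeric_density_maximum(self):
        rate = 1e4
        Fg = np.linspace(1.0, 200.0, 2_000_001)
        pdf = bell_evans_density(Fg, rate, self.DX, self.KOFF0, self.KBT)
        f_num = Fg[np.argmax(pdf)]
        f_ana = most_probable_force(rate, self.DX, self.KOFF0, self.KBT)
        assert abs(f_ana - f_num) < 0.1

    def test_tenfold_rate_shifts_mode_by_kbt_over_dx_ln10(self):
        f1 = most_probable_force(1e4, self.DX, self.KOFF0, self.KBT)
        f2 = most_probable_force(1e5, self.DX, self.KOFF0, self.KBT)
        assert f2 - f1 == pytest.approx(self.KBT / self.DX * np.log(10.0), abs=1e-9)

    def test_histogram_method_close_to_mle(self):
        rate = 1e4
        samp = self._sample(rate, 2000, 7)
        mle = fit_bell_evans(samp, rate, method="mle")
        hist = fit_bell_evans(samp, rate, method="histogram")
        assert hist.dx == pytest.approx(mle.dx, rel=0.15)


class TestCompareSpectra:
    def test_identical_samples(self):
        s = np.linspace(50, 120, 40)
        stat, p = compare_force_spectra(s, s)
        assert stat == 0.0
        assert p == 1.0

    def test_shifted_samples_distinguished(self, rng):
        a = rng.normal(80, 10, 100)
        stat, p = compare_force_spectra(a, a + 50.0)
        assert p < 0.01

    def test_exchangeable(self, rng):
        a, b = rng.normal(80, 10, 60), rng.normal(85, 12, 70)
        assert compare_force_spectra(a, b) == compare_force_spectra(b, a)


class TestSimulatePulling:
    def test_huge_off_rate_ruptures_immediately(self):
        curve = simulate_pulling([PullingSegment(40.0, 0.4, 1e6)],
                                 initial_contour=30.0, noise_sd=0.0, seed=1)
        events_zone = curve.force[:50]
        assert events_zone.max() < 20.0  # segment gone at near-zero force

    def test_same_seed_reproducible(self):
        c1 = simulate_pulling([PullingSegment(45.0, 0.4, 0.25)], seed=9)
        c2 = simulate_pulling([PullingSegment(45.0, 0.4, 0.25)], seed=9)
        assert np.array_equal(c1.force, c2.force)

    def test_rupture_histogram_matches_bell_evans_on_linear_ramp(self):
        """With a short stiff tether the ramp is nearly linear, so rupture
        forces drawn by the simulator's hazard integration follow the
        constant-rate Bell-Evans density."""
        from scipy import stats as sps

        dt = 0.01 / 1600.0  # fine steps: the force ramp must be smooth
        passes = 0
        for meta in range(5):
            forces = []
            for i in range(150):
                curve = simulate_pulling(
                    [PullingSegment(30.0, 0.4, 0.25)], initial_contour=2.0,
                    noise_sd=0.0, seed=meta * 1000 + i, velocity=1600.0,
                    spring_constant=100.0, dt=dt, f_detach=250.0)
                F = curve.force
                drop = np.nonzero(np.diff(F) < -20.0)[0]
                if drop.size:
                    forces.append(F[: drop[0] + 1].max())
            forces = np.array(forces)
            # effective (nearly constant) loading rate from the mean ramp
            curve = simulate_pulling([PullingSegment(1e9, 1e-9, 1e-30)],
                                     initial_contour=2.0, noise_sd=0.0,
                                     seed=0, f_detach=250.0, dt=dt)
            t, F = curve.time, curve.force
            band = (F > np.percentile(forces, 20)) & (F < np.percentile(forces, 80))
            rate = np.polyfit(t[band], F[band], 1)[0]
            Fg = np.linspace(0.0, 300.0, 30_000)
            pdf = bell_evans_density(Fg, rate, 0.4, 0.25, 4.11)
            cdf = np.cumsum(pdf)
            cdf /= cdf[-1]
            res = sps.ks_1samp(forces, lambda v: np.interp(v, Fg, cdf))
            if res.pvalue > 0.05:
                passes += 1
        assert passes >= 4
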