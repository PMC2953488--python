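"""WHAM reconstruction, histogram oracle, landmark extraction, profile SD."""

import math

import numpy as np
import pytest

from glycopmf import (
    KB,
    DEFAULT_POTENTIAL,
    PMFProfile,
    UmbrellaWindow,
    direct_histogram_pmf,
    landmarks,
    profile_sd,
    wham,
)
from glycopmf.errors import ConnectivityError, ConvergenceError

KBT = KB * 300.0
TINY_K = 1e-9  # effectively unbiased window


def common_g(profile, lo, hi):
    mask = profile.populated & (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    return profile.bin_centers[mask], profile.G[mask]


class TestDirectHistogram:
    def test_uniform_samples_give_flat_profile(self):
        rng = np.random.default_rng(0)
        prof = direct_histogram_pmf(rng.uniform(0, 1, 200_000), bin_width=0.05)
        x, g = common_g(prof, 0.05, 0.95)
        assert g.max() - g.min() < 0.05

    def test_gaussian_samples_recover_harmonic_well(self):
        # Boltzmann inversion of N(0, sigma): G = kBT x^2 / (2 sigma^2) + const
        rng = np.random.default_rng(1)
        sigma = 0.5
        prof = direct_histogram_pmf(rng.normal(0, sigma, 400_000), bin_width=0.05)
        x, g = common_g(prof, -1.0, 1.0)
        expected = KBT * x**2 / (2 * sigma**2)
        expected -= expected.min()
        assert np.max(np.abs(g - expected)) < 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            direct_histogram_pmf(np.array([]))


class TestWham:
    def test_equals_histogram_oracle_on_unbiased_data(self):
        """Single effectively-unbiased window: WHAM must reduce to Boltzmann
        inversion of the raw histogram."""
        rng = np.random.default_rng(2)
        samples = rng.normal(0.0, 0.4, 100_000)
        samples = samples[np.abs(samples) < 1.2]  # keep the histogram contiguous
        w = UmbrellaWindow(center=0.0, k=TINY_K, samples=samples)
        prof_w = wham([w], bin_width=0.02)
        prof_h = direct_histogram_pmf(samples, bin_width=0.02)
        both = prof_w.populated & prof_h.populated
        diff = prof_w.G[both] - prof_h.G[both]
        assert np.max(np.abs(diff)) < 0.05

    def test_boltzmann_inversion_of_harmonic_sampling(self):
        # samples from exp(-U/kBT) with U = 0.5 * 2.0 * x^2 at 300 K
        rng = np.random.default_rng(3)
        sigma = math.sqrt(KBT / 2.0)
        samples = rng.normal(0.0, sigma, 100_000)
        samples = samples[np.abs(samples) < 3.2 * sigma]  # keep the histogram contiguous
        prof = wham([UmbrellaWindow(center=0.0, k=TINY_K, samples=samples)], bin_width=0.02)
        x, g = common_g(prof, -1.0, 1.0)
        expected = 0.5 * 2.0 * x**2
        expected -= expected.min()
        assert np.max(np.abs(g - expected)) < 0.1

    def test_flat_potential_multi_window(self):
        """Biased windows on a flat landscape must reconstruct a flat profile."""
        rng = np.random.default_rng(4)
        k = 50.0
        sigma = math.sqrt(KBT / k)
        windows = []
        for c in np.linspace(0.0, 0.4, 5):
            s = rng.normal(c, sigma, 100_000)
            windows.append(UmbrellaWindow(center=c, k=k,
                                          samples=s[np.abs(s - c) < 3.2 * sigma]))
        prof = wham(windows, bin_width=0.02)
        x, g = common_g(prof, 0.0, 0.4)
        assert g.max() - g.min() < 0.1

    def test_mirror_symmetric_setup_gives_symmetric_profile(self):
        rng = np.random.default_rng(5)
        k = 100.0
        sigma = math.sqrt(KBT / k)
        centers = np.linspace(-0.4, 0.4, 9)
        windows = [
            UmbrellaWindow(center=c, k=k, samples=rng.normal(c, sigma, 50_000))
            for c in centers
        ]
        prof = wham(windows, bin_width=0.02)
        x, g = common_g(prof, -0.3, 0.3)
        g_at_minus_x = np.interp(-x, x, g)
        assert np.max(np.abs(g - g_at_minus_x)) < 0.12

    def test_invariant_to_window_order_and_bias_offset(self, default_windows):
        sub = default_windows[8:14]
        prof_a = wham(sub)
        prof_b = wham(sub[::-1])
        shifted = [
            UmbrellaWindow(center=w.center, k=w.k, samples=w.samples,
                           label=w.label, bias_offset=3.7)
            for w in sub
        ]
        prof_c = wham(shifted)
        for other in (prof_b, prof_c):
            both = prof_a.populated & other.populated
            assert np.allclose(prof_a.G[both], other.G[both], atol=1e-5)

    def test_probability_normalized(self, default_profile):
        p = np.exp(default_profile.log_prob[default_profile.populated])
        assert p.sum() * default_profile.bin_width == pytest.approx(1.0, abs=1e-10)

    def test_anchored_at_zero(self, default_profile):
        g = default_profile.G[default_profile.populated]
        assert g.min() == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_windows_raise_connectivity_error(self):
        rng = np.random.default_rng(6)
        windows = [
            UmbrellaWindow(center=0.0, k=500.0, samples=rng.normal(0.0, 0.03, 1000)),
            UmbrellaWindow(center=2.0, k=500.0, samples=rng.normal(2.0, 0.03, 1000)),
        ]
        with pytest.raises(ConnectivityError, match="gap"):
            wham(windows, bin_width=0.02)

    def test_nonconvergence_raises_with_residual(self, default_windows):
        with pytest.raises(ConvergenceError) as err:
            wham(default_windows[:6], max_iter=2)
        assert err.value.residual is not None and err.value.residual > 0

    def test_halving_bin_width_stable_barrier(self, default_windows, default_landmarks):
        fine = wham(default_windows, bin_width=0.01)
        lm_fine = landmarks(fine, (1.3, 1.9), (2.9, 3.5))
        assert abs(lm_fine.barrier - default_landmarks.barrier) < 0.2


class TestLandmarks:
    def exact_profile(self, bin_width=0.01):
        x = np.round(np.arange(1.3, 3.5 + 1e-9, bin_width), 10)
        return PMFProfile(bin_centers=x, G=DEFAULT_POTENTIAL.energy(x),
                          counts=np.ones_like(x), temperature=300.0)

    def test_exact_grid_recovers_node_table(self):
        lm = landmarks(self.exact_profile(), (1.3, 1.9), (2.9, 3.5))
        assert lm.reactant_min == pytest.approx(1.5, abs=0.005)
        assert lm.ts_pos == pytest.approx(2.17, abs=0.005)
        assert lm.product_min == pytest.approx(3.2, abs=0.005)
        assert lm.barrier == pytest.approx(19.0, abs=0.01)
        assert lm.delta_g == pytest.approx(5.0, abs=0.01)

    def test_landmark_invariants(self, default_landmarks):
        lm = default_landmarks
        assert lm.reactant_min < lm.ts_pos < lm.product_min
        assert lm.barrier >= 0

    def test_symmetric_double_well_has_zero_delta_g(self):
        x = np.arange(-1.0, 1.0 + 1e-9, 0.01)
        g = (x**2 - 0.25) ** 2  # minima at +-0.5, barrier at 0
        prof = PMFProfile(bin_centers=x, G=g - g.min(), counts=np.ones_like(x),
                          temperature=300.0)
        lm = landmarks(prof, (-0.8, -0.2), (0.2, 0.8))
        assert lm.delta_g == pytest.approx(0.0, abs=1e-10)
        assert lm.ts_pos == pytest.approx(0.0, abs=1e-10)

    def test_monotonic_rise_has_no_interior_maximum(self):
        x = np.arange(0.0, 2.0 + 1e-9, 0.01)
        g = np.where(x < 0.5, 10 * (x - 0.5) ** 2, 5 * (x - 0.5))
        prof = PMFProfile(bin_centers=x, G=g, counts=np.ones_like(x), temperature=300.0)
        with pytest.raises(ValueError, match="no interior maximum"):
            landmarks(prof, (0.0, 1.0), (1.5, 2.0))

    def test_empty_window_rejected(self):
        prof = self.exact_profile()
        with pytest.raises(ValueError, match="no populated bins"):
            landmarks(prof, (5.0, 6.0), (2.9, 3.5))


class TestProfileSD:
    def make(self, g, counts=None):
        x = np.arange(0.0, 1.0, 0.02) + 0.01
        counts = np.ones_like(x) if counts is None else counts
        return PMFProfile(bin_centers=x, G=np.asarray(g, float), counts=counts,
                          temperature=300.0)

    def test_identical_profiles(self):
        g = np.abs(np.arange(50) - 10.0)
        a = self.make(g)
        assert profile_sd(a, a, (0.0, 1.0)) == 0.0

    def test_constant_shift_removed_by_anchoring(self):
        g = np.abs(np.arange(50) - 10.0)
        a = self.make(g)
        b = self.make(g + 2.5)
        assert profile_sd(a, b, (0.0, 1.0)) == pytest.approx(0.0, abs=1e-12)

    def test_half_bins_shifted(self):
        # +0.5 kcal/mol on exactly half the bins (minimum bin untouched):
        # rms = sqrt(0.25 / 2) = 0.35355...
        g = np.abs(np.arange(50) - 10.0).astype(float)
        bumped = g.copy()
        bumped[1::2] += 0.5  # 25 of 50 bins; min bin (even index) untouched
        a = self.make(g)
        b = self.make(bumped)
        assert profile_sd(a, b, (0.0, 1.0)) == pytest.approx(math.sqrt(0.125), abs=1e-12)

    def test_no_common_bins(self):
        g = np.arange(50.0)
        a = self.make(g)
        with pytest.raises(ValueError, match="common"):
            profile_sd(a, a, (5.0, 6.0))


class TestUmbrellaWindowValidation:
    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=0.0, k=0.0, samples=np.array([0.1]))

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=0.0, k=1.0, samples=np.array([]))

    def test_nonfinite_samples_rejected(self):
        with pytest.raises(ValueError):
            UmbrellaWindow(center=0.0, k=1.0, samples=np.array([0.1, np.nan]))
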