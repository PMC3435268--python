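"""Coupling vector closed forms, palette behavior, and trial statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats

from pacpipe.broadband import BroadbandTrace, bandpower_broadband
from pacpipe.coupling import (BinnedMeans, bin_centers, bin_index,
                              condition_contrast, coupling_palette,
                              coupling_vector, coupling_vector_polar,
                              phase_bin_means, trial_coupling_stats,
                              trial_vectors)
from pacpipe.errors import ParameterError
from pacpipe.spectral import analytic_band
from pacpipe.synthetic import (CouplingSpec, RhythmSpec, SyntheticConfig,
                               make_colored_noise, make_session)

PHI0 = 3 * np.pi / 4


def binned_from(means, K=24):
    return BinnedMeans(bin_centers(K), np.asarray(means, dtype=float),
                       np.zeros(K), np.ones(K, dtype=np.int64))


class TestPhaseBins:
    def test_bin_13_is_paper_interval(self):
        """For K=24, bin k=13 (1-based) spans (0, pi/12]."""
        K = 24
        eps = 1e-9
        assert bin_index(np.array([eps]), K)[0] == 12          # 0-based 12
        assert bin_index(np.array([np.pi / 12]), K)[0] == 12
        assert bin_index(np.array([0.0]), K)[0] == 11          # 0 not included
        assert bin_index(np.array([np.pi / 12 + eps]), K)[0] == 13

    def test_bins_partition_domain(self):
        K = 24
        centers = bin_centers(K)
        assert centers[0] == pytest.approx(-np.pi + np.pi / K)
        assert centers[-1] == pytest.approx(np.pi - np.pi / K)

    @given(st.floats(-np.pi + 1e-12, np.pi), st.sampled_from([4, 8, 24, 48]))
    @settings(max_examples=200, deadline=None)
    def test_every_phase_maps_to_one_bin(self, phi, K):
        idx = bin_index(np.array([phi]), K)[0]
        assert 0 <= idx < K
        lo = idx * 2 * np.pi / K - np.pi
        hi = (idx + 1) * 2 * np.pi / K - np.pi
        assert lo < phi + 1e-9 and phi <= hi + 1e-9

    def test_wraparound_at_minus_pi(self):
        assert bin_index(np.array([-np.pi]), 24)[0] == 23


class TestPhaseBinMeans:
    def test_cosine_of_phase_recovers_cosine_of_centers(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(-np.pi, np.pi, 200_000)
        b = np.cos(phi)
        binned = phase_bin_means(b, phi, K=24)
        # bin-width discretization only: mean over a bin of width w is
        # cos(center) * sinc(w/2)
        w = 2 * np.pi / 24
        np.testing.assert_allclose(binned.means,
                                   np.cos(binned.centers) * np.sinc(w / (2 * np.pi)),
                                   atol=0.02)

    def test_null_bins_within_3_sem(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(-np.pi, np.pi, 50_000)
        b = rng.standard_normal(50_000)
        binned = phase_bin_means(b, phi, K=24)
        assert (np.abs(binned.means) < 3 * binned.sems).mean() > 0.9
        assert np.abs(binned.means).max() < 5 * binned.sems.min()

    def test_empty_bin_flagged(self):
        phi = np.full(100, 0.1)
        binned = phase_bin_means(np.ones(100), phi, K=24)
        assert binned.has_empty
        assert np.isnan(binned.means).sum() == 23

    def test_valid_mask_excludes_samples(self):
        phi = np.linspace(-np.pi + 1e-6, np.pi, 1000)
        b = np.ones(1000)
        valid = np.zeros(1000, dtype=bool)
        valid[:500] = True
        binned = phase_bin_means(b, phi, K=4, valid=valid)
        assert binned.counts.sum() == 500


class TestCouplingVector:
    def test_unit_cosine_closed_form(self):
        z, phi = coupling_vector_polar(binned_from(np.cos(bin_centers(24))))
        assert z == pytest.approx(1.0, abs=1e-12)
        assert phi == pytest.approx(0.0, abs=1e-12)

    def test_shifted_half_cosine_closed_form(self):
        m = 0.5 * np.cos(bin_centers(24) - PHI0)
        z, phi = coupling_vector_polar(binned_from(m))
        assert z == pytest.approx(0.5, abs=1e-12)
        assert phi == pytest.approx(PHI0, abs=1e-12)

    def test_constant_bins_cancel(self):
        z, _ = coupling_vector_polar(binned_from(np.full(24, 0.7)))
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_empty_bin_errors(self):
        means = np.cos(bin_centers(24))
        binned = BinnedMeans(bin_centers(24), means, np.zeros(24),
                             np.r_[np.zeros(1, dtype=np.int64),
                                   np.ones(23, dtype=np.int64)])
        binned.means[0] = np.nan
        with pytest.raises(ParameterError):
            coupling_vector(binned)


class TestPalette:
    rate = 500.0

    @pytest.fixture(scope="class")
    def coupled_palette(self):
        cfg = SyntheticConfig(
            n_channels=1, rate=self.rate, duration_s=60.0, chi=2.0,
            rhythms=[RhythmSpec(band=(12.0, 20.0), amplitude=2.0)],
            couplings=[CouplingSpec(channel=0, depth=0.5, phase0=PHI0)],
            noise_floor=1e-3, seed=7)
        s = make_session(cfg)
        b = bandpower_broadband(s.samples[0], self.rate)
        return coupling_palette(b, s.samples[0], self.rate,
                                np.arange(1.0, 51.0), K=24)

    @staticmethod
    def row_vector(pal, i):
        return (2 / 24) * np.sum(pal.means[i] * np.exp(1j * pal.centers))

    def test_coupled_rhythm_row_near_max_with_imposed_phase(self,
                                                            coupled_palette):
        pal = coupled_palette
        amps = np.abs([self.row_vector(pal, i) for i in range(50)])
        i16 = int(np.argmin(np.abs(pal.frequencies - 16.0)))
        # a pure-tone rhythm phase-locks neighboring wavelet rows, so the
        # coupling forms a plateau around 16 Hz; the 16 Hz row sits at it
        assert amps[i16] > 0.98 * amps.max()
        assert np.angle(self.row_vector(pal, i16)) == pytest.approx(
            PHI0, abs=np.pi / 8)
        # rows far below the rhythm are much weaker (rows above it retain
        # genuine sideband-induced phase structure, as in real palettes)
        far = pal.frequencies <= 4
        assert amps[far].max() < 0.4 * amps[i16]
        # and the 16 Hz row's strongest bins clear 3*SEM
        assert (np.abs(pal.means[i16]) / pal.sems[i16]).max() > 3

    def test_colored_noise_rows_not_significant(self):
        x = make_colored_noise(60 * int(self.rate), 2.0, self.rate, seed=42)
        b = bandpower_broadband(x, self.rate)
        grid = np.arange(8.0, 51.0, 2.0)   # rows whose edge region fits 1 s
        dur = int(self.rate)
        n_sig = 0
        from pacpipe.spectral import morlet_spectrogram
        dyn = morlet_spectrogram(x, grid, self.rate)
        for i in range(len(grid)):
            phi = np.angle(dyn.coefficients[i])
            starts = np.arange(0, len(x) - dur + 1, dur)
            trials = [(b.values[s:s + dur], phi[s:s + dur],
                       ~dyn.edge[i, s:s + dur]) for s in starts]
            trials = [t for t in trials if t[2].sum() >= dur // 2]
            if trial_coupling_stats(trials).p_value < 0.01:
                n_sig += 1
        assert n_sig <= 3          # ~0.22 expected by chance over 22 rows

    def test_fixed_lag_pulses_make_diagonal_band(self):
        n = 60 * int(self.rate)
        period_samp = int(self.rate)
        tau = 0.1
        centers = np.arange(0, n, period_samp)

        def pulses(cs, width):
            out = np.zeros(n)
            for c in cs:
                lo, hi = max(0, int(c - 4 * width)), min(n, int(c + 4 * width))
                out[lo:hi] += np.exp(-(np.arange(lo, hi) - c) ** 2
                                     / (2 * width ** 2))
            return out

        volt = pulses(centers, 25.0)             # harmonic-rich pulse train
        braw = pulses(centers + int(tau * self.rate), 10.0)
        b = BroadbandTrace(values=(braw - braw.mean()) / braw.std(),
                           raw=braw, rate=self.rate, source="bandpower")
        pal = coupling_palette(b, volt, self.rate, np.arange(1.0, 7.0), K=24)
        phases = np.unwrap([np.angle(self.row_vector(pal, i))
                            for i in range(6)])
        slope = np.polyfit(pal.frequencies, phases, 1)[0]
        # phase of max drifts linearly: the fixed time lag tau appears as a
        # phase lag 2*pi*f*tau growing with frequency
        assert slope == pytest.approx(2 * np.pi * tau, rel=0.3)

    def test_amplitude_invariance(self, coupled_palette):
        # scaling the rhythm (and whole signal) leaves the palette unchanged:
        # phases are amplitude-free and B is z-scored
        cfg = SyntheticConfig(
            n_channels=1, rate=self.rate, duration_s=60.0, chi=2.0,
            rhythms=[RhythmSpec(band=(12.0, 20.0), amplitude=2.0)],
            couplings=[CouplingSpec(channel=0, depth=0.5, phase0=PHI0)],
            noise_floor=1e-3, seed=7)
        s = make_session(cfg)
        x = 3.7 * s.samples[0]
        b = bandpower_broadband(x, self.rate)
        pal = coupling_palette(b, x, self.rate, np.arange(1.0, 51.0), K=24)
        np.testing.assert_allclose(pal.means, coupled_palette.means,
                                   atol=1e-9)


class TestTrialStats:
    def test_identical_vectors(self):
        z = np.full(10, 0.3 * np.exp(1j * 1.0), dtype=complex)
        stats = trial_coupling_stats(z)
        np.testing.assert_allclose(stats.zeta, 0.3)
        assert stats.sem == pytest.approx(0.0, abs=1e-12)
        assert stats.mean == pytest.approx(0.3)

    def test_mean_zeta_equals_mean_vector_magnitude(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(40) + 1j * rng.standard_normal(40) + 0.5
        stats = trial_coupling_stats(z)
        assert stats.mean == pytest.approx(abs(z.mean()), abs=1e-12)

    def test_uniform_phases_not_significant(self):
        rng = np.random.default_rng(4)
        z = 0.8 * np.exp(1j * rng.uniform(-np.pi, np.pi, 400))
        stats = trial_coupling_stats(z)
        assert stats.mean < 0.15          # -> 0 as trials grow
        assert stats.p_value > 0.05

    def test_too_few_trials(self):
        with pytest.raises(ParameterError):
            trial_coupling_stats(np.array([1 + 0j]))

    def test_type_i_error_calibrated(self):
        """Rejection rate within the 95% binomial interval of nominal alpha."""
        rng = np.random.default_rng(7)
        n_sim, n_trials, n_samp = 500, 30, 300
        pvals = []
        for _ in range(n_sim):
            trials = []
            for _ in range(n_trials):
                b = rng.standard_normal(n_samp)
                phi = np.angle(np.exp(1j * (
                    2 * np.pi * 16 * np.arange(n_samp) / n_samp
                    + rng.uniform(-np.pi, np.pi))))
                trials.append((b, phi))
            pvals.append(trial_coupling_stats(trials).p_value)
        pvals = np.array(pvals)
        for alpha in (0.05, 0.01):
            k = (pvals < alpha).sum()
            lo, hi = sstats.binom.interval(0.95, n_sim, alpha)
            assert lo <= k <= hi, f"alpha={alpha}: {k} not in [{lo},{hi}]"

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(8)
        phi = rng.uniform(-np.pi, np.pi, 40_000)
        b = np.cos(phi - 0.5) + 0.1 * rng.standard_normal(40_000)
        theta = 1.1
        z0 = coupling_vector(phase_bin_means(b, phi, 24))
        phi_shift = np.angle(np.exp(1j * (phi + theta)))
        z1 = coupling_vector(phase_bin_means(b, phi_shift, 24))
        assert abs(z1) == pytest.approx(abs(z0), rel=0.01)
        assert np.angle(z1 / z0) == pytest.approx(theta, abs=0.02)


class TestConditionContrast:
    def make_stats(self, depth, seed, n_trials=100):
        rng = np.random.default_rng(seed)
        trials = []
        for _ in range(n_trials):
            phi = rng.uniform(-np.pi, np.pi, 500)
            b = depth * np.cos(phi - PHI0) + rng.standard_normal(500)
            trials.append((b, phi))
        return trial_coupling_stats(trials)

    def test_identical_distributions_zero(self):
        s = self.make_stats(0.5, 1)
        r2, _ = condition_contrast(s, s)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_rest_coupled_vs_movement_uncoupled(self):
        rest = self.make_stats(0.5, 2)
        movement = self.make_stats(0.0, 3)
        r2, p = condition_contrast(rest, movement, direction=rest.mean_vector)
        assert r2 > 0 and p < 0.01

    def test_antisymmetry(self):
        a = self.make_stats(0.5, 4, n_trials=50)
        b = self.make_stats(0.2, 5, n_trials=50)
        direction = b.mean_vector
        r2_ab, p_ab = condition_contrast(a, b, direction=direction)
        r2_ba, p_ba = condition_contrast(b, a, direction=direction)
        assert r2_ab == pytest.approx(-r2_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_needs_two_trials(self):
        a = self.make_stats(0.5, 6, n_trials=5)
        b = trial_coupling_stats(np.array([1 + 0j, 1 + 0j]))
        with pytest.raises(ParameterError):
            condition_contrast(a, trial_coupling_stats(np.array([1 + 0j])))
        # two trials is the minimum and works
        condition_contrast(a, b)


class TestTrialVectorsFromSegments:
    def test_segments_give_one_vector_each(self, rest_coupled_session,
                                           beta_phase_rest):
        s = rest_coupled_session
        b = bandpower_broadband(s.samples[0], s.rate)
        dur = int(s.rate)
        starts = np.arange(0, s.n_samples - dur + 1, dur)[:20]
        trials = [(b.values[t:t + dur], beta_phase_rest[t:t + dur])
                  for t in starts]
        z = trial_vectors(trials, K=24)
        assert z.shape == (20,)
        stats = trial_coupling_stats(trials)
        assert stats.p_value < 0.01   # imposed coupling is detected
        assert abs(np.angle(np.exp(1j * (stats.phi_c - PHI0)))) < np.pi / 6
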