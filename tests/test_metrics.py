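"""Trace statistics against brute-force constructions and closed forms."""

import numpy as np
import pytest

from camprelay.metrics import (bootstrap_ci, calibrate_units, detect_spikes,
                               entrainment_quality, firing_rate,
                               mean_cell_rate, oscillation_period,
                               population_firing_rate, spike_width,
                               std_increase)
from camprelay.population import EnsembleTrace
from camprelay.stimulus import pulse_train_protocol


def triangle(times, t_peak, half_width, height, baseline=-1.4):
    """Triangular excursion rising above 0 around t_peak."""
    y = np.full_like(times, baseline)
    m = np.abs(times - t_peak) < half_width
    y[m] = height * (1 - np.abs(times[m] - t_peak) / half_width) + baseline
    return y


class TestDetectSpikes:
    def test_constant_below_baseline(self):
        t = np.arange(0, 10, 0.01)
        assert len(detect_spikes(t, np.full_like(t, -1.4))) == 0

    def test_two_triangles_brute_force(self):
        t = np.arange(0, 40, 0.01)
        y = triangle(t, 10.0, 3.0, 2.4) + triangle(t, 25.0, 3.0, 2.9) + 1.4
        spikes = detect_spikes(t, y)
        assert len(spikes) == 2
        assert spikes.spike_times == pytest.approx([10.0, 25.0], abs=0.02)
        assert spikes.spike_heights == pytest.approx([1.0, 1.5], abs=0.02)

    def test_one_spike_per_excursion(self):
        # two local maxima above 0 inside one excursion -> one spike
        t = np.arange(0, 10, 0.01)
        y = 0.5 + 0.4 * np.sin(2 * np.pi * t)  # always above 0: one excursion
        assert len(detect_spikes(t, y)) == 1

    def test_min_height_filter(self):
        t = np.arange(0, 20, 0.01)
        y = triangle(t, 5.0, 2.0, 1.6) + triangle(t, 14.0, 2.0, 2.2) + 1.4
        spikes = detect_spikes(t, y, min_height=0.5)
        assert len(spikes) == 1 and spikes.spike_times[0] == pytest.approx(14.0, abs=0.02)

    def test_short_noise_crossings_suppressed(self):
        t = np.arange(0, 10, 0.01)
        y = np.full_like(t, -0.5)
        y[500:503] = 0.2  # 3-sample blip < 5-sample minimum
        assert len(detect_spikes(t, y)) == 0

    def test_translation_and_scaling_invariance(self):
        t = np.arange(0, 40, 0.01)
        y = triangle(t, 10.0, 3.0, 2.4) + triangle(t, 25.0, 3.0, 2.9) + 1.4
        s1 = detect_spikes(t, y)
        s2 = detect_spikes(t + 17.0, 3.0 * y, baseline=0.0)
        assert np.allclose(s2.spike_times - 17.0, s1.spike_times)
        assert len(s2) == len(s1)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_spikes([0, 1], [0, 1])


class TestFiringRate:
    def test_count_over_duration(self):
        t = np.arange(0, 60, 0.01)
        y = np.full_like(t, -1.4)
        for c in (10, 20, 30, 40, 50):
            m = np.abs(t - c) < 2.0
            y[m] = 2.4 * (1 - np.abs(t[m] - c) / 2.0) - 1.4
        spikes = detect_spikes(t, y)
        assert firing_rate(spikes, 50.0) == pytest.approx(0.1)

    def test_empty_is_zero(self):
        t = np.arange(0, 10, 0.01)
        spikes = detect_spikes(t, np.full_like(t, -1.0))
        assert firing_rate(spikes, 10.0) == 0.0

    def test_nonpositive_duration_rejected(self):
        t = np.arange(0, 10, 0.01)
        spikes = detect_spikes(t, np.full_like(t, -1.0))
        with pytest.raises(ValueError):
            firing_rate(spikes, 0.0)

    def test_ensemble_mean(self):
        assert mean_cell_rate([0.1, 0.2, 0.3]) == pytest.approx(0.2)

    def test_additivity_over_windows(self):
        # concatenating two windows gives the duration-weighted mean rate
        def train(duration, centers):
            t = np.arange(0, duration, 0.01)
            y = np.full_like(t, -1.4)
            for c in centers:
                m = np.abs(t - c) < 2.0
                y[m] = 2.4 * (1 - np.abs(t[m] - c) / 2.0) - 1.4
            return y

        y1 = train(30, [10, 20])
        y2 = train(70, [35])
        r1 = firing_rate(detect_spikes(np.arange(0, 30, 0.01), y1), 30.0)
        r2 = firing_rate(detect_spikes(np.arange(0, 70, 0.01), y2), 70.0)
        t_cat = np.arange(0, 100, 0.01)
        r_cat = firing_rate(detect_spikes(t_cat, np.concatenate([y1, y2])),
                            100.0)
        assert r_cat == pytest.approx((30 * r1 + 70 * r2) / 100.0)


class TestPopulationRate:
    def _ensemble(self, phases, rate, duration=300.0, duty=0.2):
        """Stereotyped -1.4-baseline spike trains with given phase offsets."""
        t = np.arange(0, duration, 0.05)
        period = 1.0 / rate
        rows = []
        for ph in phases:
            y = np.full_like(t, -1.4)
            for k in range(int(duration / period) + 1):
                c = ph + k * period
                m = np.abs(t - c) < duty * period / 2
                y[m] = 2.0
            rows.append(y)
        A = np.asarray(rows)
        return EnsembleTrace(t, A, np.zeros_like(A), np.zeros_like(t))

    def test_unison_population_rate_matches_cell_rate(self):
        ens = self._ensemble(np.zeros(10), rate=0.05)
        pop = population_firing_rate(ens)
        cell = firing_rate(detect_spikes(ens.times, ens.A[0]),
                           ens.times[-1] - ens.times[0])
        assert abs(pop - cell) <= 1.0 / (ens.times[-1] - ens.times[0])

    def test_incoherent_population_rate_vanishes(self):
        # independent uniform phases, duty cycle 0.2: mean stays below 0
        rng = np.random.default_rng(0)
        ens = self._ensemble(rng.uniform(0, 20.0, size=100), rate=0.05)
        assert np.all(ens.mean_A < 0)
        assert population_firing_rate(ens) == 0.0

    def test_silent_population(self):
        t = np.arange(0, 300, 0.05)
        silent = EnsembleTrace(t, np.full((3, len(t)), -1.4),
                               np.zeros((3, len(t))), np.zeros_like(t))
        assert population_firing_rate(silent) == 0.0


class TestSpikeWidth:
    def test_triangular_width_brute_force(self):
        t = np.arange(0, 30, 0.01)
        y = np.zeros_like(t) - 1e-9
        m = (t >= 10.0) & (t <= 14.0)
        y[m] = 1.0 - np.abs(t[m] - 12.0) / 2.0  # rises at 10, returns at 14
        w = spike_width(t, y, stimulus_onset=5.0, baseline=0.0,
                        rise_fraction=0.0)
        assert w == pytest.approx(4.0, abs=0.05)

    def test_no_excursion_gives_sentinel(self):
        t = np.arange(0, 30, 0.01)
        w = spike_width(t, np.full_like(t, -1.0), stimulus_onset=5.0)
        assert np.isnan(w)

    def test_unreturned_excursion_gives_sentinel(self):
        t = np.arange(0, 30, 0.01)
        y = np.where(t > 10, 1.0, -1.0)
        assert np.isnan(spike_width(t, y, stimulus_onset=5.0))

    def test_pre_onset_excursion_ignored(self):
        t = np.arange(0, 30, 0.01)
        y = triangle(t, 3.0, 2.0, 2.4) + 1.4  # excursion before the onset
        assert np.isnan(spike_width(t, y, stimulus_onset=10.0))


class TestOscillationPeriod:
    def test_pure_tone(self):
        t = np.arange(0, 350, 0.05)
        p = oscillation_period(t, np.sin(2 * np.pi * t / 7.0))
        # within one frequency-bin width of the zero-padded grid
        bin_width = 1.0 / (4 * 350.0)
        f = 1.0 / p
        assert abs(f - 1.0 / 7.0) <= bin_width * 1.5

    def test_white_noise_undefined(self, rng):
        t = np.arange(0, 100, 0.05)
        assert np.isnan(oscillation_period(t, rng.standard_normal(len(t))))

    def test_resampling_stability(self):
        t1 = np.arange(0, 200, 0.1)
        t2 = np.arange(0, 200, 0.05)
        y = lambda t: np.sin(2 * np.pi * t / 9.0) + 0.2 * np.sin(2 * np.pi * t / 3.1)
        p1 = oscillation_period(t1, y(t1))
        p2 = oscillation_period(t2, y(t2))
        f_bin = 1.0 / (4 * 200.0)
        assert abs(1 / p1 - 1 / p2) < f_bin


class TestEntrainment:
    def _protocol(self, n=10, period=5.0, width=1.0):
        return pulse_train_protocol(10.0, width, period, n)

    def test_periodic_response_scores_one(self):
        proto = self._protocol()
        t = np.arange(0, proto.t_end, 0.01)
        y = np.sin(2 * np.pi * t / 5.0) + 0.3 * np.cos(4 * np.pi * t / 5.0)
        assert entrainment_quality(t, y, proto) == pytest.approx(1.0, abs=1e-9)

    def test_negated_second_window(self):
        proto = self._protocol(n=2)
        t = np.arange(0, proto.t_end, 0.01)
        first = np.sin(2 * np.pi * t[t < 5.0] / 5.0)
        y = np.concatenate([first, -first])[:len(t)]
        assert entrainment_quality(t, y, proto) == pytest.approx(-1.0, abs=1e-9)

    def test_noise_windows_near_zero(self, rng):
        proto = self._protocol(n=10, period=10.0)
        t = np.arange(0, proto.t_end, 0.01)  # 1000-sample windows
        q = entrainment_quality(t, rng.standard_normal(len(t)), proto)
        assert abs(q) < 0.1

    def test_brute_force_pearson_agreement(self, rng):
        proto = self._protocol(n=3, period=4.0)
        t = np.arange(0, proto.t_end, 0.01)
        y = rng.standard_normal(len(t)) + np.sin(t)
        q = entrainment_quality(t, y, proto)
        n_win = int(round(4.0 / 0.01))
        wins = [y[k * n_win:(k + 1) * n_win] for k in range(3)]

        def pearson(u, v):
            u = u - u.mean()
            v = v - v.mean()
            return float(u @ v / np.sqrt((u @ u) * (v @ v)))

        expected = np.mean([pearson(wins[0], wins[1]),
                            pearson(wins[0], wins[2])])
        assert q == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_window_rejected(self):
        proto = self._protocol(n=3)
        t = np.arange(0, proto.t_end, 0.01)
        with pytest.raises(ValueError, match="window"):
            entrainment_quality(t, np.zeros_like(t), proto)


class TestBootstrap:
    def test_constant_samples(self):
        est, (lo, hi) = bootstrap_ci(np.full(20, 3.3), seed=0)
        assert est == lo == hi == pytest.approx(3.3)

    def test_ci_contains_mean(self):
        est, (lo, hi) = bootstrap_ci([1, 2, 3, 4, 5], seed=0)
        assert lo <= 3.0 <= hi and est == 3.0

    def test_normal_half_width_matches_sem(self, rng):
        x = rng.standard_normal(100)
        _, (lo, hi) = bootstrap_ci(x, n_boot=2000, seed=1)
        half = (hi - lo) / 2.0
        assert half == pytest.approx(1.96 / np.sqrt(100), rel=0.3)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0], seed=0)


class TestStdIncrease:
    def _conditions(self, rng):
        t = np.arange(0, 100, 0.1)
        base = rng.standard_normal((10, len(t)))
        return t, {"ref": base, "same": base.copy(), "double": 2.0 * base}

    def test_reference_ratio_is_one(self, rng):
        t, conds = self._conditions(rng)
        out = std_increase(conds, t, (10, 60), "ref", n_boot=200, seed=0)
        assert out["same"][0] == pytest.approx(1.0)

    def test_scaling_homogeneity(self, rng):
        t, conds = self._conditions(rng)
        out = std_increase(conds, t, (10, 60), "ref", n_boot=200, seed=0)
        assert out["double"][0] == pytest.approx(2.0)

    def test_missing_reference(self, rng):
        t, conds = self._conditions(rng)
        with pytest.raises(KeyError):
            std_increase(conds, t, (10, 60), "nope")


class TestCalibration:
    def test_time_unit_positive_and_stable(self, params):
        T, amp = calibrate_units(params, n_amplitude_runs=5, seed=0)
        assert np.isfinite(T) and T > 0
        # the frozen preset constant tracks the calibrated minimum period
        from camprelay.stimulus import TIME_UNITS_PER_MIN
        assert T == pytest.approx(TIME_UNITS_PER_MIN, rel=0.02)
        assert amp > 1.0  # full-size accommodation spikes
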