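import numpy as np
import pytest
from nirsleep.optics import convert_recording
from nirsleep.synthetic import SimulationConfig, simulate, simulate_timeline, simulate_vitals, simulate_recording
from nirsleep.vitals import (
    AdaptiveBandState,
    default_hr_band,
    dominant_frequency,
    extract_vitals,
    interpolate_1hz,
    iqr_envelope,
    sliding_windows,
)

FS = 100.0


def tone(freq, duration=30.0, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(0, duration, 1 / fs))


def states(val):
    return {s: val for s in ("AS", "QS", "Wake")}


class TestSlidingWindows:
    def test_count_formula_60s(self):
        segs, centers = sliding_windows(np.zeros(6000), FS)
        assert len(segs) == 5  # floor((60-30)/7.5)+1
        assert np.allclose(centers, [15.0, 22.5, 30.0, 37.5, 45.0])

    def test_single_window_boundary(self):
        segs, _ = sliding_windows(np.zeros(3000), FS)
        assert len(segs) == 1

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            sliding_windows(np.zeros(2900), FS)


class TestDominantFrequency:
    def test_single_tone(self):
        f = dominant_frequency(tone(2.5), FS, (1.5, 4.0))
        assert abs(f - 2.5) < 0.01

    def test_out_of_band_tone_ignored(self):
        x = tone(2.5) + 3.0 * tone(0.8)
        f = dominant_frequency(x, FS, (1.5, 4.0))
        assert abs(f - 2.5) < 0.01

    def test_constant_segment_gives_no_estimate(self):
        assert dominant_frequency(np.full(3000, 7.0), FS, (1.5, 4.0)) is None

    def test_noise_only_gives_no_estimate(self):
        rng = np.random.default_rng(0)
        assert dominant_frequency(rng.normal(0, 1, 3000), FS, (1.5, 4.0)) is None

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            dominant_frequency(tone(2.5), FS, (1.0, 60.0))

    def test_oracle_equivalence_fine_grid_periodogram(self):
        """Matches an exhaustive fine-grid DFT argmax oracle within 0.02 Hz."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            f_true = rng.uniform(1.6, 3.9)
            x = tone(f_true) + 0.2 * rng.normal(0, 1, 3000)
            est = dominant_frequency(x, FS, (1.5, 4.0), min_prominence=0.0)
            # oracle: brute-force |DFT| on a 1 mHz grid via explicit correlation
            grid = np.arange(1.5, 4.0, 0.001)
            d = x - np.polyval(np.polyfit(np.arange(len(x)), x, 1),
                               np.arange(len(x)))
            d = d * np.hanning(len(d))
            t = np.arange(len(d)) / FS
            power = [abs(np.sum(d * np.exp(-2j * np.pi * g * t))) for g in grid]
            oracle = grid[int(np.argmax(power))]
            assert abs(est - oracle) < 0.02


class TestAdaptiveBand:
    def test_band_recenters_on_median_of_last_five(self):
        st = default_hr_band()
        for f in (2.0, 2.1, 2.2, 2.3, 2.4):
            st.update(f)
        assert st.band == (2.2 - 0.5, 2.2 + 0.5)

    def test_band_clipped_to_hard_limits(self):
        st = default_hr_band()
        for _ in range(5):
            st.update(1.35)
        assert st.band[0] >= 1.3

    def test_invalid_initial_band_rejected(self):
        with pytest.raises(ValueError):
            AdaptiveBandState(band=(0.1, 5.0), hard_limits=(1.3, 4.2))


class TestExtractVitals:
    def test_constant_hr_recovered_within_one_bpm(self):
        cfg = SimulationConfig(seed=1, duration=5, hr_wander_sd=0.0, rr_wander_sd=0.0,
                               hr_range_by_state=states((150.0, 150.0)),
                               motion_rate_by_state=states(0.0))
        rec, _, truth = simulate(cfg)
        v = extract_vitals(convert_recording(rec)[0].thb, fs=FS)
        assert np.all(np.abs(v.hr - 150.0) <= 1.0)

    def test_constant_rr_recovered_within_two_epm(self):
        cfg = SimulationConfig(seed=2, duration=5, hr_wander_sd=0.0, rr_wander_sd=0.0,
                               rr_range_by_state=states((48.0, 48.0)),
                               motion_rate_by_state=states(0.0))
        rec, _, truth = simulate(cfg)
        v = extract_vitals(convert_recording(rec)[0].thb, fs=FS)
        assert np.all(np.abs(v.rr - 48.0) <= 2.0)

    def test_hr_ramp_tracked(self):
        """HR ramp 120->160 over 10 min: estimates track truth to < 2 BPM RMSE."""
        cfg = SimulationConfig(seed=3, duration=10, hr_wander_sd=0.0,
                               motion_rate_by_state=states(0.0))
        tl = simulate_timeline(cfg, np.random.default_rng(3))
        truth = simulate_vitals(tl, cfg, np.random.default_rng(3))
        truth.hr_trace = np.linspace(120.0, 160.0, len(truth.hr_trace))
        rec, _ = simulate_recording(truth, cfg, np.random.default_rng(3))
        v = extract_vitals(convert_recording(rec)[0].thb, fs=FS)
        truth_w = np.array([truth.hr_trace[int(c - 15):int(c + 15)].mean()
                            for c in v.times])
        rmse = np.sqrt(np.mean((v.hr - truth_w) ** 2))
        assert rmse < 2.0

    def test_no_cardiac_component_flags_all_windows(self):
        cfg = SimulationConfig(seed=4, duration=4, cardiac_amplitude=0.0,
                               resp_amplitude=0.0, am_depth=0.0,
                               motion_rate_by_state=states(0.0))
        rec, _, _ = simulate(cfg)
        v = extract_vitals(convert_recording(rec)[0].thb, fs=FS)
        assert v.hr_flagged.all()

    def test_zero_respiratory_modulation_flags_rr(self):
        cfg = SimulationConfig(seed=5, duration=4, resp_amplitude=0.0, am_depth=0.0,
                               motion_rate_by_state=states(0.0))
        rec, _, _ = simulate(cfg)
        v = extract_vitals(convert_recording(rec)[0].thb, fs=FS)
        assert v.rr_flagged.all()

    def test_rr_step_settles_within_three_windows(self):
        cfg = SimulationConfig(seed=6, duration=10, rr_wander_sd=0.0,
                               motion_rate_by_state=states(0.0))
        tl = simulate_timeline(cfg, np.random.default_rng(6))
        truth = simulate_vitals(tl, cfg, np.random.default_rng(6))
        n = len(truth.rr_trace)
        truth.rr_trace = np.where(np.arange(n) < n // 2, 40.0, 60.0)
        rec, _ = simulate_recording(truth, cfg, np.random.default_rng(6))
        v = extract_vitals(convert_recording(rec)[0].thb, fs=FS)
        after = v.times > n // 2 + 3 * 7.5 + 15
        assert np.all(np.abs(v.rr[after] - 60.0) < 4.0)

    def test_band_discipline(self, sim_10min, hemo_10min):
        v = extract_vitals(hemo_10min.thb, fs=FS)
        assert np.all(v.hr >= 60 * 1.3) and np.all(v.hr <= 60 * 4.2)
        assert np.all(v.rr >= 60 * 0.25) and np.all(v.rr <= 60 * 1.7)

    def test_stride_arithmetic_matches_formula(self, hemo_10min):
        v = extract_vitals(hemo_10min.thb, fs=FS)
        expected = int((600 - 30) // 7.5) + 1
        assert len(v.hr) == expected


class TestIqrEnvelope:
    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            iqr_envelope(np.zeros(10), FS)

    def test_gain_invariant(self):
        rng = np.random.default_rng(0)
        x = tone(2.5) + 0.1 * rng.normal(0, 1, 3000)
        e1, _ = iqr_envelope(x, FS)
        e2, _ = iqr_envelope(50.0 * x, FS)
        assert np.allclose(e1, e2, atol=1e-9)


class TestInterpolate1Hz:
    def make_vitals(self, hr, rr=None):
        from nirsleep.types import VitalsSeries
        n = len(hr)
        t = 15.0 + 7.5 * np.arange(n)
        rr = rr if rr is not None else np.full(n, 48.0)
        return VitalsSeries(times=t, hr=np.asarray(hr, dtype=float),
                            rr=np.asarray(rr, dtype=float),
                            hr_flagged=np.zeros(n, bool), rr_flagged=np.zeros(n, bool))

    def test_constant_reproduced(self):
        v = interpolate_1hz(self.make_vitals(np.full(6, 150.0)))
        assert np.allclose(v.hr_1hz, 150.0)

    def test_knot_values_exact(self):
        hr = np.array([140.0, 150.0, 145.0, 155.0, 150.0])
        v = interpolate_1hz(self.make_vitals(hr))
        # t=30 s is both a knot (window 3 center) and an integer second
        assert v.hr_1hz[np.where(v.times_1hz == 30.0)[0][0]] == pytest.approx(hr[2])

    def test_linear_trend_reproduced(self):
        hr = 120.0 + 2.0 * np.arange(8)
        v = interpolate_1hz(self.make_vitals(hr))
        expected = 120.0 + 2.0 * (v.times_1hz - 15.0) / 7.5
        assert np.allclose(v.hr_1hz, expected, atol=1e-9)

    def test_fewer_than_four_estimates_rejected(self):
        with pytest.raises(ValueError, match="4"):
            interpolate_1hz(self.make_vitals(np.full(3, 150.0)))
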