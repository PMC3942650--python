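"""Feature extraction: background SD, waves, interpeak latencies, thresholds."""

import math

import numpy as np
import pytest

from ratabr.abr_features import (
    DEFAULT_SEARCH_WINDOWS,
    IntensitySeries,
    background_sd,
    detect_threshold,
    detect_waves,
    interpeak,
    peak_to_peak,
)
from ratabr.errors import ConfigurationError, InputError
from ratabr.synthetic_data import (
    DEFAULT_INTENSITIES,
    DEFAULT_TEMPLATES,
    AgeEffect,
    WaveTemplate,
    simulate_abr,
    simulate_series,
    true_threshold,
)

from conftest import make_recording


class TestBackgroundSD:
    def test_constant_prestimulus_gives_zero(self):
        rec = make_recording(np.full(375, 3.0))
        assert background_sd(rec) == 0.0

    def test_hand_computed_sample_sd(self):
        # sample SD (n-1) of [-1, 1, -1, 1] is sqrt(4/3) = 1.1547
        rec = make_recording([-1.0, 1.0, -1.0, 1.0, 0.0, 0.0],
                             sampling_rate=4000.0, onset_index=4)
        assert background_sd(rec) == pytest.approx(math.sqrt(4.0 / 3.0), abs=1e-9)

    def test_recovers_generating_sd(self):
        rng = np.random.default_rng(123)
        noise = rng.normal(0, 0.5, size=10_500)
        rec = make_recording(noise, sampling_rate=1_000_000.0, onset_index=10_000)
        est = background_sd(rec)
        # independent recomputation of the sample SD on the same fixture
        seg = noise[:10_000]
        manual = math.sqrt(((seg - seg.mean()) ** 2).sum() / (len(seg) - 1))
        assert est == pytest.approx(manual, abs=1e-12)
        assert est == pytest.approx(0.5, abs=0.02)

    def test_too_short_prestimulus_rejected(self):
        rec = make_recording(np.zeros(375), onset_index=10)
        with pytest.raises(InputError):
            background_sd(rec)  # 10 samples at 25 kHz = 0.4 ms < 1 ms


class TestPeakToPeak:
    def test_flat_trace_zero(self, flat_recording):
        assert peak_to_peak(flat_recording) == 0.0

    def test_max_minus_min(self):
        x = np.zeros(375)
        x[150], x[200] = 2.0, -1.5
        assert peak_to_peak(make_recording(x)) == pytest.approx(3.5)

    def test_equals_bruteforce_pairwise_scan(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=375)
        rec = make_recording(x)
        seg = rec.post_segment(0.0, 8.0)
        brute = max(a - b for a in seg for b in seg)
        assert peak_to_peak(rec) == pytest.approx(brute, abs=1e-12)

    def test_empty_window_rejected(self, flat_recording):
        with pytest.raises(InputError):
            peak_to_peak(flat_recording, (3.0, 3.0))


class TestDetectWaves:
    def test_transit_correction_rule(self, young):
        tpl = WaveTemplate("I", base_amplitude=2.0, base_peak_latency=1.5,
                           latency_slope=0.0, width=0.2)
        rec = simulate_abr([tpl], young, 0.5, 80, noise_sd=0.0, seed=0)
        waves = detect_waves(rec)
        assert len(waves) == 1
        dt = 1000.0 / rec.sampling_rate
        assert waves[0].positive_latency == pytest.approx(2.0, abs=dt)
        assert waves[0].positive_latency - waves[0].peak_time == pytest.approx(0.5)
        assert waves[0].negative_latency - waves[0].trough_time == pytest.approx(0.5)

    def test_flat_trace_yields_no_waves(self, flat_recording):
        assert detect_waves(flat_recording) == []

    def test_five_wave_recovery_against_closed_form(self, young):
        """Noiseless five-wave trace: peak times within one sample of the
        template centres, amplitudes within 1% of the analytic peak-to-peak."""
        fs = 200_000.0
        rec = simulate_abr(DEFAULT_TEMPLATES, young, 8, 80, noise_sd=0.0,
                           sampling_rate=fs, seed=0)
        waves = {w.wave_id: w for w in detect_waves(rec)}
        dt = 1000.0 / fs
        for tpl in DEFAULT_TEMPLATES:
            w = waves[tpl.wave_id]
            assert abs(w.peak_time - tpl.base_peak_latency) <= dt + 1e-12
            assert abs(w.trough_time - (tpl.base_peak_latency + tpl.width)) <= dt + 1e-12
            assert w.amplitude == pytest.approx(tpl.base_amplitude, rel=0.01)

    def test_trough_always_follows_peak(self, young):
        rec = simulate_abr(DEFAULT_TEMPLATES, young, 4, 80, noise_sd=0.3, seed=9)
        for w in detect_waves(rec):
            assert w.trough_time > w.peak_time
            assert w.amplitude >= 0

    def test_time_reversed_trace_gives_different_features(self, young):
        rec = simulate_abr(DEFAULT_TEMPLATES, young, 4, 80, noise_sd=0.0, seed=0)
        waves = detect_waves(rec)
        rev = make_recording(rec.samples[::-1].copy(), onset_index=rec.onset_index)
        rev_waves = detect_waves(rev)
        assert [(w.wave_id, w.peak_time) for w in waves] != \
               [(w.wave_id, w.peak_time) for w in rev_waves]

    def test_overlapping_windows_rejected(self, flat_recording):
        bad = dict(DEFAULT_SEARCH_WINDOWS)
        bad["II"] = (1.0, 2.5)  # overlaps window I
        with pytest.raises(ConfigurationError):
            detect_waves(flat_recording, bad)


class TestInterpeak:
    def test_pairwise_differences(self):
        from ratabr.abr_features import WaveFeature

        def wf(wid, pos):
            return WaveFeature(wid, pos - 0.5, pos - 0.3, 1.0, -1.0, 2.0,
                               pos, pos + 0.2)

        ip = interpeak([wf("I", 2.0), wf("II", 3.0), wf("IV", 4.5)])
        assert ip.PI_PII == pytest.approx(1.0)
        assert ip.PII_PIV == pytest.approx(1.5)
        assert ip.PI_PIV == pytest.approx(2.5)
        assert ip.PI_PIV == pytest.approx(ip.PI_PII + ip.PII_PIV, abs=1e-15)
        assert ip.missing_waves == ()

    def test_identical_latencies_give_zeros(self):
        from ratabr.abr_features import WaveFeature
        waves = [WaveFeature(w, 1.0, 1.2, 1.0, -1.0, 2.0, 1.5, 1.7)
                 for w in ("I", "II", "IV")]
        ip = interpeak(waves)
        assert ip.PI_PII == ip.PII_PIV == ip.PI_PIV == 0.0

    def test_missing_wave_flagged(self):
        from ratabr.abr_features import WaveFeature
        ip = interpeak([WaveFeature("I", 1.0, 1.2, 1, -1, 2, 1.5, 1.7)])
        assert "II" in ip.missing_waves and "IV" in ip.missing_waves
        assert ip.PI_PII is None and ip.PI_PIV is None

    def test_uniform_delay_cancels_in_interpeak(self, young):
        """A uniform latency delay (sample-aligned, 0.16 ms at 25 kHz) shifts
        every wave equally, so the interpeak latencies match the young group's."""
        freqs = (4.0,)
        delayed = AgeEffect("delayed",
                            threshold_shift={4.0: 0.0},
                            amplitude_factor={4.0: 1.0},
                            latency_delay={4.0: 0.16})
        rec_y = simulate_abr(DEFAULT_TEMPLATES, AgeEffect.young(freqs), 4.0, 80,
                             noise_sd=0.0, seed=0)
        rec_d = simulate_abr(DEFAULT_TEMPLATES, delayed, 4.0, 80,
                             noise_sd=0.0, seed=0)
        ip_y = interpeak(detect_waves(rec_y))
        ip_d = interpeak(detect_waves(rec_d))
        for name in ("PI_PII", "PII_PIV", "PI_PIV", "NI_NII", "NII_NIV", "NI_NIV"):
            assert getattr(ip_d, name) == pytest.approx(getattr(ip_y, name), abs=1e-9)


class TestDetectThreshold:
    def test_noiseless_series_recovers_constructed_threshold(self, young, templates):
        series = simulate_series(templates, young, 0.5, noise_sd=0.0)
        truth = true_threshold(young, 0.5, DEFAULT_INTENSITIES)
        res = detect_threshold(series)
        assert res.threshold == truth == 50

    def test_no_signal_series_gives_no_response(self, young, templates):
        # degenerate: zero signal at every intensity (deaf ear, clean average)
        deaf = AgeEffect("deaf", threshold_shift={0.5: 60.0},
                         amplitude_factor={0.5: 1.0}, latency_delay={0.5: 0.0})
        series = simulate_series(templates, deaf, 0.5, noise_sd=0.0)
        res = detect_threshold(series)
        assert res.is_no_response
        assert res.label == "no-response"

    def test_uniform_shift_moves_threshold_equally(self, templates):
        """+10 dB of simulated threshold shift raises the detected threshold
        by exactly 10 dB (noiseless)."""
        freqs = (4.0,)
        base = AgeEffect.young(freqs)
        shifted = AgeEffect("shifted", threshold_shift={4.0: 10.0},
                            amplitude_factor={4.0: 1.0}, latency_delay={4.0: 0.0})
        t0 = detect_threshold(simulate_series(templates, base, 4.0, noise_sd=0.0))
        t1 = detect_threshold(simulate_series(templates, shifted, 4.0, noise_sd=0.0))
        assert t1.threshold == t0.threshold + 10

    def test_criterion_bracket_at_threshold(self, young, templates):
        """At the detected threshold the response exceeds the criterion; one
        step below (when tested) it does not."""
        series = simulate_series(templates, young, 2, noise_sd=0.0)
        res = detect_threshold(series)
        t = res.threshold
        assert res.per_intensity_pp[t] > res.criterion_sd[t]
        below = t - 5
        if below in res.per_intensity_pp:
            assert res.per_intensity_pp[below] <= res.criterion_sd[below]

    def test_gapped_grid_rejected(self, young, templates):
        recs = [simulate_abr(templates, young, 4, i, 0.0) for i in (80, 75, 65)]
        with pytest.raises(InputError):
            IntensitySeries(recs)

    def test_audit_trail_covers_every_intensity(self, young, templates):
        series = simulate_series(templates, young, 8, noise_sd=0.0)
        res = detect_threshold(series)
        assert sorted(res.per_intensity_pp) == sorted(series.intensities)
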