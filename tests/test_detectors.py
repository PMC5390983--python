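"""The five detectors: front-end, thresholds, gates and classification."""

import numpy as np
import pytest

from hfobench.background import low_hf_model, high_hf_model, synthesize_background
from hfobench.detectors import (
    DelphosParams,
    HILParams,
    MNIParams,
    bandpass_80_500,
    detect_delphos,
    detect_hil,
    detect_mni,
    detect_sll,
    detect_ste,
    run_detector,
)
from hfobench.detectors.delphos import hfo_oscillations
from hfobench.detectors.hil import envelope
from hfobench.detectors.sll import line_length_energy
from hfobench.events import make_synthetic_hfo, make_synthetic_spike
from hfobench.simulate import insert_spike, scale_to_snr

FS = 2048.0


@pytest.fixture(scope="module")
def bkg60():
    return synthesize_background(low_hf_model(), 60.0, seed=21)


@pytest.fixture(scope="module")
def bkg20(bkg60):
    return bkg60[: int(20 * FS)].copy()


def _insert(bkg, tmpl, t_s, snr_db):
    w = scale_to_snr(tmpl, bkg, snr_db, fs=FS)
    x = bkg.copy()
    i0 = int(t_s * FS) - w.size // 2
    x[i0 : i0 + w.size] += w
    return x


class TestBandpass:
    def test_passband_gain_near_unity(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 300.0 * t)
        y = bandpass_80_500(x, FS)
        mid = slice(int(FS), int(3 * FS))
        gain_db = 20 * np.log10(np.abs(y[mid]).max() / np.abs(x[mid]).max())
        assert abs(gain_db) < 0.5

    def test_stopband_attenuation(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_80_500(x, FS)
        mid = slice(int(FS), int(3 * FS))
        assert 20 * np.log10(np.abs(y[mid]).max()) < -60.0

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass_80_500(np.zeros(8192), FS), 0.0)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            bandpass_80_500(np.zeros(4096), 800.0)


class TestSTE:
    def test_pure_background_has_few_detections(self, bkg60):
        out = detect_ste(bkg60, FS)
        assert len(out.detections) <= 3  # null behavior, count recorded loosely
        rms_trace_scale = np.sqrt(np.mean(bandpass_80_500(bkg60, FS) ** 2))
        assert out.threshold > rms_trace_scale  # threshold sits above the bulk

    def test_eight_cycle_burst_detected_once(self, bkg60):
        x = _insert(bkg60, make_synthetic_hfo(150.0, 8.0, FS), 30.0, 20.0)
        out = detect_ste(x, FS)
        hits = [d for d in out.detections if d.t_start_s < 30.03 and d.t_end_s > 29.97]
        assert len(hits) == 1

    def test_two_cycle_burst_fails_peak_count(self, bkg60):
        tmpl = make_synthetic_hfo(150.0, 4.0, FS)
        tmpl.waveform = tmpl.waveform[: int(2 / 150 * FS)]  # truncate to 2 cycles
        x = _insert(bkg60, tmpl, 30.0, 20.0)
        hits = [
            d
            for d in detect_ste(x, FS).detections
            if d.t_start_s < 30.05 and d.t_end_s > 29.95
        ]
        assert hits == []


class TestSLL:
    def test_constant_signal_silent(self):
        out = detect_sll(np.full(int(15 * FS), 2.5), FS)
        assert out.detections == []

    def test_line_length_energy_window_sum(self, rng):
        x = rng.normal(size=1000)
        e = line_length_energy(x, 25)
        k = 600
        assert e[k] == pytest.approx(np.sum(np.abs(np.diff(x[k - 24 : k + 1]))))

    def test_fast_burst_outscores_slow_burst_at_equal_band_snr(self, bkg60):
        # second differencing boosts high frequencies: at the same band SNR
        # a 400 Hz burst must reach a larger peak line-length energy
        x400 = _insert(bkg60, make_synthetic_hfo(400.0, 8.0, FS), 30.0, 10.0)
        x120 = _insert(bkg60, make_synthetic_hfo(120.0, 8.0, FS), 30.0, 10.0)

        def peak_near(out, t):
            s = [d.score for d in out.detections if abs(d.t_peak_s - t) < 0.1]
            return max(s) if s else 0.0

        assert peak_near(detect_sll(x400, FS), 30.0) > peak_near(detect_sll(x120, FS), 30.0)


class TestHIL:
    def test_unmodulated_tone_no_detections(self):
        t = np.arange(int(15 * FS)) / FS
        out = detect_hil(np.sin(2 * np.pi * 200.0 * t), FS)
        assert out.detections == []  # near-constant envelope, no div-by-zero

    def test_duration_gate_separates_12ms_from_8ms(self, bkg20):
        bp = bandpass_80_500(bkg20, FS)
        env = envelope(bp)
        thr = env.mean() + 5 * env.std()
        hits = {}
        for dur_ms in (12.0, 8.0):
            n = int(dur_ms / 1000 * FS)
            burst = 1.5 * thr * np.sin(2 * np.pi * 250.0 * np.arange(n) / FS)
            x = bkg20.copy()
            x[int(10 * FS) : int(10 * FS) + n] += burst
            out = detect_hil(x, FS)
            hits[dur_ms] = [d for d in out.detections if abs(d.t_peak_s - 10.0) < 0.05]
        assert len(hits[12.0]) == 1 and hits[8.0] == []

    def test_threshold_inflated_by_large_spike(self, bkg20):
        base = detect_hil(bkg20, FS).threshold
        spiked = insert_spike(
            bkg20, make_synthetic_spike(80.0, 2.5, FS), 10.0, 1.0, 15.0, 0.0, fs=FS
        )
        assert detect_hil(spiked, FS).threshold > base

    def test_pure_sd_flag_lowers_threshold(self, bkg20):
        full = detect_hil(bkg20, FS)
        pure = detect_hil(bkg20, FS, HILParams(pure_sd=True))
        assert pure.threshold < full.threshold


class TestMNI:
    def test_mode_switch_tracks_high_frequency_power(self):
        low = detect_mni(synthesize_background(low_hf_model(), 60.0, 1), FS)
        high = detect_mni(synthesize_background(high_hf_model(), 60.0, 1), FS)
        assert low.extras["mode"] == "baseline"
        assert high.extras["mode"] == "iterative"
        assert high.extras["baseline_fraction"] < low.extras["baseline_fraction"]

    def test_baseline_mode_has_fewer_fps_than_forced_iterative(self, bkg60):
        auto = detect_mni(bkg60, FS)
        forced = detect_mni(bkg60, FS, MNIParams(min_baseline_frac=1.1))
        assert auto.extras["mode"] == "baseline"
        assert forced.extras["mode"] == "iterative"
        assert len(auto.detections) <= len(forced.detections)

    def test_iterative_threshold_decreases_with_large_bursts(self, bkg60):
        x = bkg60.copy()
        for i, t_s in enumerate(np.linspace(10.0, 50.0, 5)):
            x = _insert(x, make_synthetic_hfo(150.0, 8.0, FS), t_s, 25.0)
        out = detect_mni(x, FS, MNIParams(min_baseline_frac=1.1))
        hist = out.extras["threshold_history"]
        assert hist[-1] < hist[0]

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="10 s"):
            detect_mni(np.zeros(int(5 * FS)), FS)


class TestDelphos:
    def test_tone_oscillation_impulse_spike(self, bkg20):
        x = bkg20.copy()
        t = np.arange(int(2 * FS)) / FS
        x[int(5 * FS) : int(5 * FS) + t.size] += (
            5 * np.std(bkg20) * np.sin(2 * np.pi * 150.0 * t)
        )
        x[int(12 * FS)] += 50 * np.std(bkg20)
        out = detect_delphos(x, FS)
        tone_types = {
            d.type for d in out.detections if d.t_start_s < 6.5 and d.t_end_s > 5.5
        }
        imp_types = {d.type for d in out.detections if abs(d.t_peak_s - 12.0) < 0.05}
        assert tone_types == {"oscillation"}
        assert imp_types == {"spike"}

    def test_hfo_classified_in_band_across_frequencies(self, bkg20):
        for f0 in (100.0, 250.0, 450.0):
            x = _insert(bkg20, make_synthetic_hfo(f0, 8.0, FS), 8.0, 15.0)
            osc = hfo_oscillations(
                [d for d in detect_delphos(x, FS).detections if abs(d.t_peak_s - 8.0) < 0.06]
            )
            assert len(osc) == 1
            assert osc[0].peak_freq_hz == pytest.approx(f0, rel=0.15)

    def test_pure_background_rarely_fires(self):
        # tail probability of normalized energy > 30 is ~1e-13 per pixel
        clean = 0
        for seed in range(20):
            bkg = synthesize_background(low_hf_model(), 60.0, seed=300 + seed)
            clean += not hfo_oscillations(detect_delphos(bkg, FS).detections)
        assert clean >= 19

    def test_fast_ripple_riding_spike_detected(self, bkg20):
        z = insert_spike(
            bkg20, make_synthetic_spike(80.0, 2.0, FS), 8.0, 1.0, 10.0, 0.5, fs=FS
        )
        w = scale_to_snr(make_synthetic_hfo(350.0, 8.0, FS), bkg20, 15.0, fs=FS)
        i0 = int(8 * FS) - w.size // 2
        z[i0 : i0 + w.size] += w
        osc = hfo_oscillations(
            [d for d in detect_delphos(z, FS).detections if abs(d.t_peak_s - 8.0) < 0.08]
        )
        assert len(osc) >= 1 and osc[0].peak_freq_hz > 250.0

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            detect_delphos(np.zeros(1000), FS)


class TestDispatch:
    def test_all_detectors_deterministic(self, bkg20):
        for name in ("ste", "sll", "hil", "mni", "delphos"):
            a = run_detector(name, bkg20, FS)
            b = run_detector(name, bkg20, FS)
            assert [
                (d.t_start_s, d.t_end_s, d.type) for d in a.detections
            ] == [(d.t_start_s, d.t_end_s, d.type) for d in b.detections]
            assert a.threshold == b.threshold

    def test_unknown_detector_rejected(self, bkg20):
        with pytest.raises(ValueError, match="unknown detector"):
            run_detector("nope", bkg20, FS)
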