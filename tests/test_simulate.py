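"""Benchmark generator: timings, SNR scaling, insertion, reproducibility."""

import numpy as np
import pytest

from hfobench.events import (
    BROADBAND,
    RIPPLE_BAND,
    band_power,
    make_synthetic_hfo,
    make_synthetic_spike,
)
from hfobench.simulate import (
    MIN_EVENT_SPACING_S,
    SimulationConfig,
    draw_event_timeline,
    generate_channel,
    insert_spike,
    scale_to_snr,
)
from hfobench.background import synthesize_background

FS = 2048.0


def _cfg(**kw):
    return SimulationConfig(**kw)


class TestTimeline:
    def test_poisson_count_within_three_sd(self):
        cfg = _cfg(class_rates={5: 3.0}, duration_s=3600.0)
        events = draw_event_timeline(cfg, seed=1)
        assert abs(len(events) - 180) <= 3 * np.sqrt(180)

    def test_single_active_class_dominates(self):
        cfg = _cfg(class_rates={c: (3.0 if c == 5 else 0.0) for c in range(1, 8)})
        events = draw_event_timeline(cfg, seed=2)
        assert events and all(c == 5 for _, c in events)

    def test_minimum_spacing_enforced(self):
        cfg = _cfg(class_rates={5: 40.0}, duration_s=120.0)
        times = [t for t, _ in draw_event_timeline(cfg, seed=3)]
        assert np.min(np.diff(times)) >= MIN_EVENT_SPACING_S

    def test_deterministic_given_seed(self):
        cfg = _cfg()
        assert draw_event_timeline(cfg, seed=4) == draw_event_timeline(cfg, seed=4)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            draw_event_timeline(_cfg(duration_s=2.0), seed=0)


@pytest.fixture(scope="module")
def bkg20():
    from hfobench.background import low_hf_model

    return synthesize_background(low_hf_model(), 20.0, seed=5)


@pytest.fixture(scope="module")
def bkg10():
    from hfobench.background import low_hf_model

    return synthesize_background(low_hf_model(), 10.0, seed=6)


class TestScaleToSNR:
    @pytest.fixture()
    def bkg(self, bkg20):
        return bkg20

    def test_zero_db_matches_background_band_power(self, bkg):
        tmpl = make_synthetic_hfo(150.0, 8.0, FS)
        scaled = scale_to_snr(tmpl, bkg, 0.0, fs=FS)
        ratio = band_power(scaled, tmpl.band, FS) / band_power(bkg, tmpl.band, FS)
        assert ratio == pytest.approx(1.0, rel=0.02)

    def test_ten_db_is_ten_fold(self, bkg):
        tmpl = make_synthetic_hfo(300.0, 6.0, FS)
        scaled = scale_to_snr(tmpl, bkg, 10.0, fs=FS)
        ratio = band_power(scaled, tmpl.band, FS) / band_power(bkg, tmpl.band, FS)
        assert ratio == pytest.approx(10.0, rel=0.05)

    def test_homogeneous_in_background_amplitude(self, bkg):
        tmpl = make_synthetic_hfo(150.0, 8.0, FS)
        a = scale_to_snr(tmpl, bkg, 5.0, fs=FS)
        b = scale_to_snr(tmpl, 2.0 * bkg, 5.0, fs=FS)
        assert np.allclose(b, 2.0 * a)

    def test_zero_energy_template_rejected(self, bkg):
        tmpl = make_synthetic_hfo(150.0, 8.0, FS)
        tmpl.waveform = np.zeros_like(tmpl.waveform)
        with pytest.raises(ValueError, match="zero-energy"):
            scale_to_snr(tmpl, bkg, 0.0, fs=FS)


class TestInsertSpike:
    @pytest.fixture()
    def bkg(self, bkg10):
        return bkg10

    def test_no_silencing_is_pure_addition(self, bkg):
        spike = make_synthetic_spike(80.0, 1.0, FS)
        out = insert_spike(bkg, spike, 5.0, k=1.0, snr_db=10.0, silencing_depth=0.0, fs=FS)
        diff = out - bkg
        assert np.count_nonzero(diff) == spike.waveform.size
        scaled = scale_to_snr(spike, bkg, 10.0, fs=FS)
        i0 = int(round(5.0 * FS)) - scaled.size // 2
        assert np.allclose(diff[i0 : i0 + scaled.size], scaled)

    def test_full_silencing_zeroes_background_at_center(self, bkg):
        spike = make_synthetic_spike(80.0, 1.0, FS)
        out = insert_spike(bkg, spike, 5.0, k=1.0, snr_db=10.0, silencing_depth=1.0, fs=FS)
        scaled = scale_to_snr(spike, bkg, 10.0, fs=FS)
        i0 = int(round(5.0 * FS)) - scaled.size // 2
        mid = slice(i0 + scaled.size // 2 - 5, i0 + scaled.size // 2 + 5)
        assert np.allclose(out[mid], scaled[scaled.size // 2 - 5 : scaled.size // 2 + 5])

    def test_stretch_doubles_duration(self, bkg):
        spike = make_synthetic_spike(80.0, 1.0, FS)

        def width_above_10pct(w):
            idx = np.flatnonzero(np.abs(w) > 0.1 * np.abs(w).max())
            return idx[-1] - idx[0] + 1

        base = insert_spike(np.zeros_like(bkg), spike, 5.0, 1.0, 0.0, 0.0, fs=FS,
                            bkg_broadband_power=band_power(bkg, BROADBAND, FS))
        double = insert_spike(np.zeros_like(bkg), spike, 5.0, 2.0, 0.0, 0.0, fs=FS,
                              bkg_broadband_power=band_power(bkg, BROADBAND, FS))
        assert width_above_10pct(double) == pytest.approx(2 * width_above_10pct(base), abs=2)

    def test_out_of_record_support_rejected(self, bkg):
        spike = make_synthetic_spike(80.0, 1.0, FS)
        with pytest.raises(ValueError, match="outside"):
            insert_spike(bkg, spike, 0.01, 1.0, 0.0, 0.0, fs=FS)


class TestGenerateChannel:
    def test_spike_only_config_has_no_hfo_components(self, low_model, dictionary):
        cfg = _cfg(class_rates={1: 6.0}, duration_s=30.0)
        ch = generate_channel(low_model, dictionary, cfg, 10.0, 7)
        assert ch.ground_truth
        assert ch.hfo_components() == []

    def test_inserted_ripple_band_power_matches_snr(self, low_model, dictionary):
        # isolated R at 15 dB: signal minus event-free twin, re-measured in
        # the ripple band over the component support, is ~31.6x background
        cfg = _cfg(class_rates={5: 4.0}, duration_s=60.0)
        ch = generate_channel(low_model, dictionary, cfg, 15.0, 8)
        twin = synthesize_background(
            low_model, cfg.duration_s, np.random.default_rng(
                np.random.SeedSequence([8]).spawn(3)[0]
            ),
        )
        # twin must equal the background the generator used
        silent = generate_channel(low_model, dictionary, _cfg(class_rates={5: 0.0, 6: 0.001}, duration_s=60.0), 15.0, 8)
        p_bkg = band_power(twin, RIPPLE_BAND, FS)
        checked = 0
        for class_id, comp in ch.hfo_components():
            if class_id != 5:
                continue
            events_only = ch.samples - twin
            i0 = int(round((comp.t_center_s - 0.04) * FS))
            i1 = int(round((comp.t_center_s + 0.04) * FS))
            seg = events_only[i0:i1]
            support = np.flatnonzero(np.abs(seg) > 0)
            seg = seg[support[0] : support[-1] + 1]
            ratio = band_power(seg, RIPPLE_BAND, FS) / p_bkg
            assert 10 * np.log10(ratio) == pytest.approx(15.0, abs=1.0)
            checked += 1
        assert checked >= 2

    def test_zero_rates_reproduce_plain_background(self, low_model, dictionary):
        cfg = _cfg(class_rates={c: 0.0 for c in range(1, 8)}, duration_s=20.0)
        ch = generate_channel(low_model, dictionary, cfg, 10.0, 9)
        ss = np.random.SeedSequence([9])
        twin = synthesize_background(
            low_model, 20.0, np.random.default_rng(ss.spawn(3)[0])
        )
        assert np.array_equal(ch.samples, twin)

    def test_bit_identical_for_identical_seed(self, low_model, dictionary):
        cfg = _cfg(duration_s=20.0)
        a = generate_channel(low_model, dictionary, cfg, 10.0, 10)
        b = generate_channel(low_model, dictionary, cfg, 10.0, 10)
        assert np.array_equal(a.samples, b.samples)
        assert a.ground_truth == b.ground_truth

    def test_jitter_only_on_cooccurring_hfos(self, low_model, dictionary):
        cfg = _cfg(class_rates={5: 5.0, 7: 5.0}, duration_s=60.0, jitter_ms=20.0)
        ch = generate_channel(low_model, dictionary, cfg, 10.0, 11)
        for ev in ch.ground_truth:
            for c in ev.components:
                if ev.class_id == 5:
                    assert c.jitter_s == 0.0
                else:
                    assert abs(c.jitter_s) <= 0.020


def test_ground_truth_component_structure_enforced():
    from hfobench.simulate import GroundTruthComponent, GroundTruthEvent

    with pytest.raises(ValueError, match="components"):
        GroundTruthEvent(4, 1.0, [GroundTruthComponent("R", 1.0, 10.0)])
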