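"""Detector fidelity, thresholds, epoch handling and co-occurrence gating."""

import warnings

import numpy as np
import pandas as pd
import pytest

from sospindle import (Hypnogram, Recording, SimConfig, detect_slow_oscillations,
                       detect_spindles, cooccurrence_rate, gate_cooccurrence,
                       generate_recording, znorm_epochs)
from sospindle.events import EVENT_COLUMNS, EventSet, amplitude_threshold_mask
from sospindle.spectral import OscillatoryPeaks
from sospindle.synthio import fractal_noise, spindle_waveform
from conftest import match_events

FS = 128.0


def peaks_for(channels, spindle_freq=13.0):
    rows = []
    for ch in channels:
        rows.append({"channel": ch, "band": "spindle", "peak_freq": spindle_freq,
                     "peak_amp": 1.0, "is_local_max": True})
        rows.append({"channel": ch, "band": "so", "peak_freq": 0.8,
                     "peak_amp": 1.0, "is_local_max": True})
    return OscillatoryPeaks(pd.DataFrame(rows))


def make_eventset(kind, channel, times, fs=FS, stage="N3", epoch_len=None):
    n = epoch_len or (2 * int(2.5 * fs) + 1)
    df = pd.DataFrame({
        "channel": channel, "center_time": times, "onset": np.array(times) - 0.5,
        "offset": np.array(times) + 0.5, "duration": 1.0, "amplitude": 1.0,
        "stage": stage})[EVENT_COLUMNS]
    return EventSet(kind, df, np.zeros((len(times), n)), fs)


class TestSpindleDetection:
    def test_recall_and_precision_on_planted_fixture(self, n3_recording):
        cfg, rec, hyp, truth = n3_recording
        ev = detect_spindles(rec, hyp, peaks_for(rec.channel_labels), ("N3",))
        tp, fp, fn, f1 = match_events(ev.events.center_time,
                                      truth.spindle_events.peak_time)
        assert tp / (tp + fn) >= 0.9      # recall
        assert tp / (tp + fp) >= 0.9      # precision

    def test_pure_sinusoid_yields_no_events(self):
        t = np.arange(int(60 * FS)) / FS
        rec = Recording(np.sin(2 * np.pi * 13 * t)[None, :], FS, ("Cz",))
        hyp = Hypnogram.from_plan((("N3", 60.0),))
        ev = detect_spindles(rec, hyp, peaks_for(("Cz",)), ("N3",))
        assert len(ev) == 0  # one continuous supra-threshold run > 3 s

    def test_event_near_recording_end_dropped_and_logged(self):
        rng = np.random.default_rng(0)
        n = int(120 * FS)
        x = fractal_noise(n, FS, 1.5, 1.0, rng)
        w = spindle_waveform(13.0, 30.0, 1.0, FS)
        end = n - int(1.0 * FS)
        x[end - len(w):end] += w            # peak ~1 s before the end
        x[int(60 * FS):int(60 * FS) + len(w)] += w  # control event mid-recording
        rec = Recording(x[None, :], FS, ("Cz",))
        hyp = Hypnogram.from_plan((("N3", 120.0),))
        ev = detect_spindles(rec, hyp, peaks_for(("Cz",)), ("N3",))
        assert ev.dropped["epoch_bounds"] >= 1
        assert np.all(ev.events.center_time < 120 - 2.5 + 1e-9)

    def test_missing_peak_frequency_raises(self, n3_recording):
        _, rec, hyp, _ = n3_recording
        with pytest.raises(KeyError):
            detect_spindles(rec, hyp, peaks_for(("F3",)), ("N3",))

    def test_gain_invariance(self, n3_recording):
        _, rec, hyp, _ = n3_recording
        pk = peaks_for(rec.channel_labels)
        ev1 = detect_spindles(rec, hyp, pk, ("N3",))
        rec10 = Recording(rec.signal * 10, rec.sampling_rate, rec.channel_labels)
        ev2 = detect_spindles(rec10, hyp, pk, ("N3",))
        assert np.array_equal(ev1.events.center_time, ev2.events.center_time)

    def test_percentile_monotonicity(self, n3_recording):
        _, rec, hyp, _ = n3_recording
        pk = peaks_for(rec.channel_labels)
        counts = [len(detect_spindles(rec, hyp, pk, ("N3",), percentile=p))
                  for p in (70, 80, 90, 97)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_false_positive_floor_on_pure_noise(self, noise_recording):
        """The quantile threshold inevitably fires on pure noise; the
        documented false-alarm floor is a few events per minute."""
        rec, hyp = noise_recording
        ev = detect_spindles(rec, hyp, peaks_for(("Cz",)), ("N3",))
        density = len(ev) / hyp.minutes(("N3",))
        assert 0 < density < 8.0

    def test_epochs_inside_recording(self, n3_recording):
        _, rec, hyp, _ = n3_recording
        ev = detect_spindles(rec, hyp, peaks_for(rec.channel_labels), ("N3",))
        assert (ev.events.center_time >= 2.5).all()
        assert (ev.events.center_time <= rec.duration - 2.5).all()
        assert ev.epochs.shape[1] == 2 * int(2.5 * FS) + 1


class TestSODetection:
    def test_planted_train_matched(self, n3_recording):
        cfg, rec, hyp, truth = n3_recording
        ev = detect_slow_oscillations(rec, hyp, ("N3",))
        tp, fp, fn, f1 = match_events(ev.events.center_time,
                                      truth.so_events.trough_time)
        assert tp / (tp + fn) >= 0.9

    def test_fast_sinusoid_fails_time_criterion(self):
        t = np.arange(int(60 * FS)) / FS
        rec = Recording(np.sin(2 * np.pi * 3 * t)[None, :], FS, ("Cz",))
        hyp = Hypnogram.from_plan((("N3", 60.0),))
        ev = detect_slow_oscillations(rec, hyp, ("N3",))
        assert len(ev) == 0  # half-wave interval 0.33 s < 0.8 s

    def test_identical_candidate_amplitudes_all_pass(self):
        mask = amplitude_threshold_mask(np.full(100, 42.0), 75)
        assert mask.all()

    def test_largest_quartile_kept(self):
        amps = np.arange(1.0, 101.0)
        mask = amplitude_threshold_mask(amps, 75)
        # interpolated threshold is 75.25, so 76..100 survive
        assert mask.sum() == 25
        assert amps[mask].min() >= np.percentile(amps, 75)

    def test_too_few_candidates_warns_and_yields_empty(self):
        rec = Recording(np.zeros((1, int(30 * FS))) + 1e-12, FS, ("Cz",))
        hyp = Hypnogram.from_plan((("N3", 30.0),))
        with pytest.warns(RuntimeWarning, match="candidates"):
            ev = detect_slow_oscillations(rec, hyp, ("N3",))
        assert len(ev) == 0

    def test_gain_invariance(self, n3_recording):
        _, rec, hyp, _ = n3_recording
        ev1 = detect_slow_oscillations(rec, hyp, ("N3",))
        rec10 = Recording(rec.signal * 10, rec.sampling_rate, rec.channel_labels)
        ev2 = detect_slow_oscillations(rec10, hyp, ("N3",))
        assert np.array_equal(ev1.events.center_time, ev2.events.center_time)


class TestZnormEpochs:
    def test_normalization_and_scale_invariance(self, n3_recording):
        _, rec, hyp, _ = n3_recording
        ev = detect_spindles(rec, hyp, peaks_for(rec.channel_labels), ("N3",))
        nz = znorm_epochs(ev)
        assert np.allclose(nz.norm_epochs.mean(axis=1), 0, atol=1e-6)
        assert np.allclose(nz.norm_epochs.std(axis=1), 1, atol=1e-6)
        ev10 = ev.select(np.arange(len(ev)))
        ev10.epochs = ev.epochs * 10
        nz10 = znorm_epochs(ev10)
        assert np.allclose(nz.norm_epochs, nz10.norm_epochs, atol=1e-9)
        assert nz.epochs is not None  # raw retained alongside

    def test_constant_epoch_dropped_with_warning(self):
        ev = make_eventset("spindle", "Cz", [10.0, 20.0])
        ev.epochs = np.vstack([np.ones(ev.epochs.shape[1]),
                               np.sin(np.arange(ev.epochs.shape[1]))])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            nz = znorm_epochs(ev)
        assert len(nz) == 1


class TestGate:
    def test_within_window_kept_with_lag(self):
        sp = make_eventset("spindle", "Cz", [100.0])
        so = make_eventset("slow_oscillation", "Cz", [101.0])
        gated = gate_cooccurrence(sp, so)
        assert len(gated) == 1
        assert gated.events.lag.iloc[0] == pytest.approx(1.0)

    def test_outside_window_dropped(self):
        sp = make_eventset("spindle", "Cz", [100.0])
        so = make_eventset("slow_oscillation", "Cz", [103.0])
        assert len(gate_cooccurrence(sp, so)) == 0

    def test_nearest_partner_chosen(self):
        sp = make_eventset("spindle", "Cz", [100.0])
        so = make_eventset("slow_oscillation", "Cz", [99.6, 102.0])
        gated = gate_cooccurrence(sp, so)
        assert gated.events.lag.iloc[0] == pytest.approx(-0.4)

    def test_channels_do_not_mix(self):
        sp = make_eventset("spindle", "Cz", [100.0])
        so = make_eventset("slow_oscillation", "Pz", [100.5])
        assert len(gate_cooccurrence(sp, so)) == 0

    def test_stage_restriction_applied_before_gating(self):
        sp = make_eventset("spindle", "Cz", [100.0], stage="N2")
        so = make_eventset("slow_oscillation", "Cz", [100.5], stage="N2")
        assert len(gate_cooccurrence(sp, so, stages=("N3",))) == 0
        assert len(gate_cooccurrence(sp, so, stages=("N2", "N3"))) == 1


class TestCooccurrenceRate:
    def test_rates_for_planted_mixtures(self):
        rng = np.random.default_rng(1)
        # 100 spindles on SOs, 100 planted >= 3 s away from any SO
        so_times = np.arange(100) * 20.0 + 10.0
        coupled = so_times + rng.uniform(-0.5, 0.5, 100)
        lonely = so_times + 10.0
        hyp = Hypnogram.from_plan((("N3", 2100.0),))
        so = make_eventset("slow_oscillation", "Cz", so_times)
        rate_c = cooccurrence_rate(
            make_eventset("spindle", "Cz", coupled), so, hyp)
        assert rate_c.rate.iloc[0] == pytest.approx(1.0)
        rate_l = cooccurrence_rate(
            make_eventset("spindle", "Cz", lonely), so, hyp)
        assert rate_l.rate.iloc[0] == pytest.approx(0.0)
        both = make_eventset("spindle", "Cz",
                             np.sort(np.r_[coupled, lonely]))
        rate_b = cooccurrence_rate(both, so, hyp)
        assert abs(rate_b.rate.iloc[0] - 0.5) <= 0.1

    def test_stage_without_spindles_is_missing_not_zero(self):
        sp = make_eventset("spindle", "Cz", [100.0], stage="N3")
        so = make_eventset("slow_oscillation", "Cz", [100.5], stage="N3")
        hyp = Hypnogram.from_plan((("N3", 300.0),))
        rates = cooccurrence_rate(sp, so, hyp)
        assert set(rates.stage) == {"N3"}  # no N2 row invented
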