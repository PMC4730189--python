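"""Spike detector: z-scoring, candidate rules, clustering, STA."""

import numpy as np
import pytest

from somnispike.config import GeneratorConfig, IISDetectionConfig
from somnispike.io_formats import Recording
from somnispike.iis import (channel_zscore, detect_candidates, detect_iis,
                            refine_templates, spike_triggered_average)
from somnispike.synthetic import biphasic_pulse, generate_recording, inject_iis

CFG = IISDetectionConfig(seed=0)


def _noise_rec(rng, n_s=60, fs=2000.0, sd=20.0):
    return Recording(samples=rng.standard_normal((4, int(n_s * fs))) * sd,
                     sample_rate=fs)


class TestChannelZscore:
    def test_null_signal_has_no_crossings(self, rng):
        rec = _noise_rec(rng)
        z = channel_zscore(rec, np.ones(rec.n_samples, dtype=bool))
        assert (np.abs(z.samples) < 3).mean() > 0.99
        assert not (np.abs(z.samples) >= 7).any()

    def test_injected_peak_recovered(self, rng):
        rec = _noise_rec(rng)
        out = inject_iis(rec, [30.0], amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        # sample |z| at the two pulse extrema (one pulse-sigma off the event)
        sigma_s = 0.040 / 6.0
        idx = [int(round((30.0 - sigma_s) * 2000)), int(round((30.0 + sigma_s) * 2000))]
        vals = np.abs(z.samples[:, idx]).ravel()
        assert 11.0 <= np.median(vals) <= 13.0

    def test_constant_channel_rejected(self):
        rec = Recording(samples=np.zeros((4, 4000)), sample_rate=2000.0)
        with pytest.raises(ValueError, match="SD"):
            channel_zscore(rec, np.ones(4000, dtype=bool))

    def test_empty_baseline_rejected(self, rng):
        rec = _noise_rec(rng, n_s=5)
        with pytest.raises(ValueError, match="baseline"):
            channel_zscore(rec, np.zeros(rec.n_samples, dtype=bool))


class TestDetectCandidates:
    def test_flat_noise_yields_nothing(self, rng):
        rec = _noise_rec(rng, n_s=120)
        z = channel_zscore(rec, np.ones(rec.n_samples, dtype=bool))
        assert detect_candidates(z, CFG) == []

    def test_injected_events_recovered_with_timing(self, rng):
        rec = _noise_rec(rng, n_s=600)
        times = np.arange(20) * 30.0 + 5.0
        out = inject_iis(rec, list(times), amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        cands = detect_candidates(z, CFG)
        assert len(cands) == 20
        for t, ev in zip(times, cands):
            assert abs(ev.onset - t) <= 0.010
            assert ev.n_channels == 4

    def test_three_channel_event_flagged(self, rng):
        rec = _noise_rec(rng, n_s=30)
        out = inject_iis(rec, [(15.0, (True, True, True, False))],
                         amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        cands = detect_candidates(z, CFG)
        assert len(cands) == 1 and cands[0].n_channels == 3

    def test_two_channel_event_dropped(self, rng):
        rec = _noise_rec(rng, n_s=30)
        out = inject_iis(rec, [(15.0, (True, True, False, False))],
                         amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        assert detect_candidates(z, CFG) == []

    def test_overlong_transient_dropped(self, rng):
        # an 80-ms threshold-crossing span violates the transience rule
        rec = _noise_rec(rng, n_s=30)
        fs = rec.sample_rate
        sd = rec.samples.std(axis=1)
        n = int(0.080 * fs)
        w = np.r_[np.ones(n // 2), -np.ones(n - n // 2)]
        out = rec.samples.copy()
        i0 = int(15.0 * fs)
        for ch in range(4):
            out[ch, i0:i0 + n] += 12.0 * sd[ch] * w
        z = channel_zscore(Recording(samples=out, sample_rate=fs),
                           np.ones(rec.n_samples, dtype=bool))
        assert detect_candidates(z, CFG) == []

    def test_count_monotone_in_threshold(self, session_20min):
        rec, truth = session_20min["rec"], session_20min["truth"]
        labels = truth.labels_on_grid()
        base = [i for i, l in enumerate(labels) if l in ("NREM", "QW")]
        z = channel_zscore(rec, base)
        counts = []
        for thr in (5.0, 6.0, 7.0, 8.0):
            cfg = IISDetectionConfig(z_threshold=thr, seed=0)
            counts.append(len(detect_candidates(z, cfg)))
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestRefineTemplates:
    def test_pure_spike_set_has_no_artifacts(self, rng):
        rec = _noise_rec(rng, n_s=600)
        times = list(np.arange(12) * 45.0 + 10.0)
        out = inject_iis(rec, times, amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        events = refine_templates(detect_candidates(z, CFG), CFG)
        assert all(ev.label == "IIS" for ev in events)

    def test_artifact_rejection_against_truth(self):
        # jittered monophasic cable artifacts that pass the amplitude rule
        # must still be sorted out by the template stage
        cfg = GeneratorConfig(
            duration_s=2400.0, seed=21,
            iis_rate_per_hour={"AW": 0, "QW": 0, "NREM": 60.0, "REM": 120.0},
            artifact_rate_per_hour=60.0,
        )
        rec, _, truth = generate_recording(cfg)
        labels = truth.labels_on_grid()
        base = [i for i, l in enumerate(labels) if l in ("NREM", "QW")]
        events = detect_iis(rec, base, IISDetectionConfig(seed=0))
        art_t = np.array(truth.artifact_times)
        iis_t = np.array([t for t, _ in truth.iis_times])
        spikes = [ev.onset for ev in events if ev.label in ("IIS", "IIS-like")]
        # no ground-truth artifact may survive as a labeled spike
        leaked = sum(1 for t in spikes
                     if art_t.size and np.min(np.abs(art_t - t)) < 0.1)
        candidates_near_art = sum(
            1 for ev in events
            if art_t.size and np.min(np.abs(art_t - ev.onset)) < 0.1)
        if candidates_near_art:
            assert 1 - leaked / candidates_near_art >= 0.9
        # and the true spikes survive
        recalled = sum(1 for t in iis_t
                       if spikes and np.min(np.abs(np.array(spikes) - t)) < 0.01)
        assert recalled / iis_t.size >= 0.9

    def test_same_seed_identical_assignments(self, rng):
        rec = _noise_rec(rng, n_s=600)
        times = list(np.arange(10) * 55.0 + 10.0)
        out = inject_iis(rec, times, amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        e1 = refine_templates(detect_candidates(z, CFG), CFG, seed=5)
        e2 = refine_templates(detect_candidates(z, CFG), CFG, seed=5)
        assert [ev.cluster_id for ev in e1] == [ev.cluster_id for ev in e2]
        assert [ev.label for ev in e1] == [ev.label for ev in e2]

    def test_few_candidates_keep_threshold_labels(self, rng):
        rec = _noise_rec(rng, n_s=60)
        out = inject_iis(rec, [20.0, 40.0], amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        events = refine_templates(detect_candidates(z, CFG), CFG)
        assert [ev.label for ev in events] == ["IIS", "IIS"]


class TestSTA:
    def test_sta_matches_injected_waveform(self, rng):
        fs = 2000.0
        rec = _noise_rec(rng, n_s=1200)
        times = list(np.arange(40) * 29.0 + 5.0)
        out = inject_iis(rec, times, amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        events = refine_templates(detect_candidates(z, CFG), CFG)
        sta = spike_triggered_average(events, out, CFG)
        assert sta.shape == (4, int(0.200 * fs))
        # oracle: the injected pulse, amplitude 12 x channel SD, at -50 ms lag
        pulse = biphasic_pulse(40.0, fs)
        sd = rec.samples.std(axis=1)
        # detector onset locks to the pulse's largest |z| extremum; align by
        # cross-correlation within +/- one pulse width before comparing
        for ch in range(4):
            expected_peak = 12.0 * sd[ch]
            assert np.max(np.abs(sta[ch])) == pytest.approx(
                expected_peak, rel=3.0 / np.sqrt(len(times)) + 0.1)

    def test_single_event_sta_is_its_snippet(self, rng):
        rec = _noise_rec(rng, n_s=30)
        out = inject_iis(rec, [15.0], amplitude_z=12.0, width_ms=40.0)
        z = channel_zscore(out, np.ones(out.n_samples, dtype=bool))
        events = refine_templates(detect_candidates(z, CFG), CFG)
        sta = spike_triggered_average(events, out, CFG)
        fs = out.sample_rate
        i0 = int(round(events[0].onset * fs)) - int(0.050 * fs)
        np.testing.assert_array_equal(sta, out.samples[:, i0:i0 + int(0.200 * fs)])

    def test_empty_events_rejected(self, rng):
        rec = _noise_rec(rng, n_s=5)
        with pytest.raises(ValueError, match="no labeled spikes"):
            spike_triggered_average([], rec, CFG)


def test_config_validation():
    with pytest.raises(ValueError, match="200"):
        IISDetectionConfig(waveform_pre_ms=60.0).validate()
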