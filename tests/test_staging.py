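"""Staging rules, REM merging, sleep episodes, SFI, and the RF classifier."""

import numpy as np
import pandas as pd
import pytest

from somnispike.config import AnalysisConfig, StagingThresholds
from somnispike.io_formats import VelocityTrace
from somnispike.spectral import EpochSpectra
from somnispike.staging import (Hypnogram, apply_state_classifier,
                                classify_epochs, find_sleep_episodes,
                                merge_rem, sleep_fragmentation_index,
                                smooth_velocity, train_state_classifier)

THR = StagingThresholds()


def make_spectra(ratios, wideband_hot):
    """Synthetic epoch spectra with prescribed theta/delta ratios and
    sustained-wideband flags (standardization pre-filled)."""
    n = len(ratios)
    cfg = AnalysisConfig()
    freqs = np.linspace(0, 500, 5001)
    power = np.zeros((n, freqs.size))
    i_delta = np.argmin(np.abs(freqs - 2.0))
    i_theta = np.argmin(np.abs(freqs - 7.5))
    for i, r in enumerate(ratios):
        power[i, i_delta] = 1.0
        power[i, i_theta] = r
    sp = EpochSpectra(freqs=freqs, power_raw=power, epoch_length_s=10.0,
                      cfg=cfg, channel_role="FC",
                      artifact=np.zeros(n, dtype=bool))
    sp.power_z = np.zeros_like(power)
    sp.sub_z = np.where(np.asarray(wideband_hot)[:, None], 5.0,
                        -0.5) * np.ones((n, 10))
    return sp


def make_velocity(moving_epochs, n_epochs, speed=5.0):
    v = np.zeros(n_epochs * 100)  # 10 Hz, 10-s epochs
    for e in moving_epochs:
        v[e * 100:(e + 1) * 100] = speed
    return VelocityTrace(values=v, sample_rate=10.0)


class TestSmoothVelocity:
    def test_constant_unchanged(self):
        v = VelocityTrace(values=np.full(500, 2.3), sample_rate=10.0)
        out = smooth_velocity(v, THR)
        np.testing.assert_allclose(out.values, 2.3, atol=1e-9)

    def test_impulse_gives_closed_form_kernel(self):
        # closed-form oracle: smoothing a unit impulse reproduces the kernel
        fs = 100.0
        v = np.zeros(1001)
        v[500] = 1.0
        out = smooth_velocity(VelocityTrace(values=v, sample_rate=fs), THR)
        sigma = 0.5 * fs
        supp = np.arange(-int(4 * sigma), int(4 * sigma) + 1)
        kernel = np.exp(-(supp ** 2) / (2 * sigma ** 2))
        kernel /= kernel.sum()
        np.testing.assert_allclose(out.values[500 + supp], kernel, atol=1e-12)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            smooth_velocity(VelocityTrace(values=np.array([]), sample_rate=10.0), THR)


class TestClassifyEpochs:
    def test_rem_requires_prior_nrem(self):
        sp = make_spectra([0.5, 3.0], wideband_hot=[True, False])
        vel = make_velocity([], 2)
        hyp = classify_epochs(sp, vel, THR)
        assert hyp.to_labels() == ["NREM", "REM"]

    def test_high_ratio_after_quiet_wake_is_not_rem(self):
        sp = make_spectra([0.5, 3.0], wideband_hot=[False, False])
        vel = make_velocity([], 2)
        hyp = classify_epochs(sp, vel, THR)
        assert hyp.to_labels() == ["QW", "QW"]

    def test_movement_dominates(self):
        sp = make_spectra([0.5, 3.0, 3.0], wideband_hot=[True, True, False])
        vel = make_velocity([1], 3)
        hyp = classify_epochs(sp, vel, THR)
        assert hyp.to_labels()[1] == "AW"

    def test_rem_can_continue(self):
        sp = make_spectra([0.5, 3.0, 3.0, 3.0], wideband_hot=[True] + [False] * 3)
        vel = make_velocity([], 4)
        assert classify_epochs(sp, vel, THR).to_labels() == \
            ["NREM", "REM", "REM", "REM"]

    def test_missing_velocity_rejected(self):
        sp = make_spectra([0.5], [True])
        with pytest.raises(ValueError):
            classify_epochs(sp, None, THR)
        with pytest.raises(ValueError, match="cover"):
            classify_epochs(sp, VelocityTrace(values=np.zeros(5), sample_rate=10.0), THR)

    def test_deterministic(self, staged_20min):
        sp, vel = staged_20min["spectra"], staged_20min["vel"]
        h1 = classify_epochs(sp, vel, THR)
        h2 = classify_epochs(sp, vel, THR)
        assert h1.to_labels() == h2.to_labels()

    def test_agreement_with_ground_truth(self, staged_20min):
        truth = staged_20min["truth"].labels_on_grid()
        pred = staged_20min["hyp"].to_labels()
        acc = np.mean([a == b for a, b in zip(truth, pred)])
        assert acc >= 0.9

    def test_rem_invariant_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = 40
            sp = make_spectra(rng.uniform(0, 5, n), rng.random(n) < 0.4)
            vel = make_velocity(np.nonzero(rng.random(n) < 0.3)[0], n)
            hyp = classify_epochs(sp, vel, THR)
            assert hyp.rem_preceded_by_nrem()


def _H(*ivs):
    return Hypnogram(intervals=list(ivs))


class TestMergeRem:
    def test_two_second_gap_merges(self):
        h = _H((0, 10, "NREM"), (10, 20, "REM"), (20, 22, "QW"), (22, 30, "REM"))
        out = merge_rem(h, THR)
        assert (10.0, 30.0, "REM") in out.intervals

    def test_four_second_gap_stays(self):
        h = _H((0, 10, "NREM"), (10, 20, "REM"), (20, 24, "QW"), (24, 30, "REM"))
        out = merge_rem(h, THR)
        labs = [iv[2] for iv in out.intervals]
        assert labs == ["NREM", "REM", "QW", "REM"]

    def test_chain_merge(self):
        h = _H((0, 10, "NREM"), (10, 12, "REM"), (12, 13, "QW"), (13, 15, "REM"),
               (15, 16.5, "AW"), (16.5, 20, "REM"))
        out = merge_rem(h, THR)
        assert out.intervals == [(0.0, 10.0, "NREM"), (10.0, 20.0, "REM")]

    def test_idempotent_on_random_hypnograms(self):
        rng = np.random.default_rng(99)
        states = ["AW", "QW", "NREM", "REM"]
        for _ in range(200):
            t, ivs = 0.0, []
            for _ in range(rng.integers(3, 25)):
                dur = float(rng.choice([0.5, 1, 2, 3, 5, 10, 30]))
                ivs.append((t, t + dur, states[rng.integers(4)]))
                t += dur
            h = Hypnogram(intervals=ivs)
            m1 = merge_rem(h, THR)
            m2 = merge_rem(m1, THR)
            assert m1.intervals == m2.intervals


# ---------------------------------------------------------------------------
# sleep episodes / SFI with an independent linear-scan oracle

from _oracles import oracle_episodes as _oracle_episodes
from _oracles import random_sleepy_hypnogram as _random_sleepy_hypnogram


class TestSleepEpisodes:
    def test_single_long_nrem_block(self):
        h = _H((0, 600, "NREM"))
        eps = find_sleep_episodes(h)
        assert len(eps) == 1
        assert eps[0].n_transitions == 0 and eps[0].n_brief_arousals == 0

    def test_short_block_discarded(self):
        h = _H((0, 240, "NREM"), (240, 300, "AW"))
        assert find_sleep_episodes(h) == []

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(4242)
        for _ in range(150):
            h = _random_sleepy_hypnogram(rng)
            got = [(e.start, e.end, e.n_transitions, e.n_brief_arousals)
                   for e in find_sleep_episodes(h)]
            exp = _oracle_episodes(h.intervals)
            assert len(got) == len(exp)
            for g, x in zip(got, exp):
                assert g[0] == pytest.approx(x[0], abs=0.5)
                assert g[1] == pytest.approx(x[1], abs=0.5)
                assert g[2:] == x[2:]


class TestSFI:
    def test_uninterrupted_episode_zero(self):
        h = _H((0, 600, "NREM"))
        res = sleep_fragmentation_index(find_sleep_episodes(h), h)
        assert res.sfi == 0.0 and res.total_count == 0

    def test_transitions_plus_arousal_enumeration(self):
        # enumeration oracle: NREM -> REM -> NREM with one 2-s arousal = 3
        h = _H((0, 240, "NREM"), (240, 360, "REM"), (360, 362, "QW"),
               (362, 600, "NREM"))
        eps = find_sleep_episodes(h)
        assert len(eps) == 1
        res = sleep_fragmentation_index(eps, h)
        assert res.total_count == 3
        assert res.per_episode.iloc[0]["n_transitions"] == 2
        assert res.per_episode.iloc[0]["n_brief_arousals"] == 1

    def test_no_sleep_warns_and_reports_zero(self):
        h = _H((0, 600, "AW"))
        with pytest.warns(UserWarning, match="SFI"):
            res = sleep_fragmentation_index(find_sleep_episodes(h), h)
        assert res.sfi == 0.0

    def test_invariant_to_relabeling_outside_episodes(self):
        h1 = _H((0, 600, "NREM"), (600, 700, "AW"))
        h2 = _H((0, 600, "NREM"), (600, 700, "QW"))
        r1 = sleep_fragmentation_index(find_sleep_episodes(h1), h1)
        r2 = sleep_fragmentation_index(find_sleep_episodes(h2), h2)
        assert r1.sfi == r2.sfi


class TestClassifier:
    def _separable(self, n_per=30, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        centers = {"AW": 0.0, "QW": 10.0, "NREM": 20.0, "REM": 30.0}
        for lab, c in centers.items():
            for _ in range(n_per):
                rows.append(c + rng.standard_normal(5) * 0.1)
                labels.append(lab)
        return pd.DataFrame(rows), labels

    def test_separable_set_perfect(self):
        X, y = self._separable()
        clf = train_state_classifier(X, y, seed=0)
        assert (clf.predict(X.to_numpy()) == np.array(y)).all()

    def test_missing_state_rejected(self):
        X, y = self._separable()
        mask = [lab != "REM" for lab in y]
        with pytest.raises(ValueError, match="REM"):
            train_state_classifier(X[mask], [l for l in y if l != "REM"], seed=0)

    def test_apply_enforces_rem_entry(self):
        X, y = self._separable()
        clf = train_state_classifier(X, y, seed=0)
        hyp = apply_state_classifier(clf, X)
        assert hyp.rem_preceded_by_nrem()

    def test_deterministic_given_seed(self):
        X, y = self._separable()
        p1 = train_state_classifier(X, y, seed=3).predict(X.to_numpy())
        p2 = train_state_classifier(X, y, seed=3).predict(X.to_numpy())
        assert (p1 == p2).all()
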