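"""Behavioral-state staging, sleep episodes and the sleep fragmentation index.

Each 10-s epoch is classified into active wakefulness (AW), quiet
wakefulness (QW), NREM or REM sleep by a fixed rule hierarchy:

1. movement above the velocity floor for more than 3 s -> AW;
2. else theta/delta power ratio > 2.5 with the running prior state NREM
   (or an ongoing REM run) -> REM;
3. else wideband power > 1 z above quiet wakefulness sustained for at
   least 3 s (three consecutive 1-s subwindows), or the optional delta
   criterion -> NREM;
4. else -> QW.

REM runs separated by less than 3 s are merged. A sleep episode begins
with NREM, tolerates brief (< 3 s) arousals, ends when an arousal lasts
3 s or longer, and counts only if longer than 5 minutes. The sleep
fragmentation index (SFI) totals NREM/REM transitions plus brief arousals
within episodes, reported per hour of episode sleep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import EPOCH_LENGTH_S, STATES, AnalysisConfig, StagingThresholds
from .io_formats import Recording, VelocityTrace
from .spectral import EpochSpectra, standardize_to_quiet_wake

__all__ = [
    "Hypnogram",
    "SleepEpisode",
    "SFIResult",
    "smooth_velocity",
    "classify_epochs",
    "merge_rem",
    "find_sleep_episodes",
    "sleep_fragmentation_index",
    "epoch_features",
    "train_state_classifier",
    "apply_state_classifier",
]

SLEEP_STATES = ("NREM", "REM")
WAKE_STATES = ("AW", "QW")


def _merge_adjacent(intervals: list[tuple[float, float, str]]) -> list[tuple[float, float, str]]:
    out: list[tuple[float, float, str]] = []
    for s, e, lab in intervals:
        if out and out[-1][2] == lab and abs(out[-1][1] - s) < 1e-9:
            out[-1] = (out[-1][0], e, lab)
        else:
            out.append((s, e, lab))
    return out


@dataclass
class Hypnogram:
    """Labeled behavioral-state intervals tiling ``[start, end)``.

    Intervals are half-open, contiguous and carry labels from
    ``{AW, QW, NREM, REM}``. Grid-born hypnograms also expose per-epoch
    labels; interval-born ones may have sub-epoch boundaries (e.g. after
    REM merging of externally scored data).
    """

    intervals: list[tuple[float, float, str]]
    epoch_length_s: float = EPOCH_LENGTH_S

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("hypnogram needs at least one interval")
        self.intervals = _merge_adjacent(
            [(float(s), float(e), str(lab)) for s, e, lab in self.intervals]
        )
        prev_end = self.intervals[0][0]
        for s, e, lab in self.intervals:
            if lab not in STATES:
                raise ValueError(f"unknown state label {lab!r}")
            if e <= s:
                raise ValueError(f"empty/reversed interval ({s}, {e})")
            if abs(s - prev_end) > 1e-9:
                raise ValueError(f"intervals do not tile: gap/overlap at {s}")
            prev_end = e

    @classmethod
    def from_labels(cls, labels: Sequence[str],
                    epoch_length_s: float = EPOCH_LENGTH_S) -> "Hypnogram":
        ivs = [(i * epoch_length_s, (i + 1) * epoch_length_s, lab)
               for i, lab in enumerate(labels)]
        return cls(intervals=ivs, epoch_length_s=epoch_length_s)

    @property
    def start(self) -> float:
        return self.intervals[0][0]

    @property
    def end(self) -> float:
        return self.intervals[-1][1]

    @property
    def duration(self) -> float:
        return self.end - self.start

    def to_labels(self, epoch_length_s: float | None = None) -> list[str]:
        """Per-epoch labels (state at each epoch midpoint)."""
        el = epoch_length_s or self.epoch_length_s
        n = int(round((self.end - self.start) / el))
        labels = []
        j = 0
        for i in range(n):
            t = self.start + (i + 0.5) * el
            while t >= self.intervals[j][1] and j < len(self.intervals) - 1:
                j += 1
            labels.append(self.intervals[j][2])
        return labels

    def label_at(self, t: float) -> str:
        if not (self.start <= t < self.end):
            raise ValueError(f"time {t} outside hypnogram span [{self.start}, {self.end})")
        for s, e, lab in self.intervals:
            if s <= t < e:
                return lab
        raise AssertionError("unreachable: intervals tile the span")

    def state_durations(self) -> dict[str, float]:
        out = {s: 0.0 for s in STATES}
        for s, e, lab in self.intervals:
            out[lab] += e - s
        return out

    def transitions(self, from_state: str | None = None,
                    to_state: str | None = None) -> list[float]:
        """Onset times of state changes, optionally filtered by edge labels."""
        times = []
        for (s0, e0, l0), (s1, e1, l1) in zip(self.intervals, self.intervals[1:]):
            if (from_state is None or l0 == from_state) and \
               (to_state is None or l1 == to_state):
                times.append(s1)
        return times

    def rem_preceded_by_nrem(self) -> bool:
        """Check the REM-entry invariant (first interval may not be REM)."""
        for i, (s, e, lab) in enumerate(self.intervals):
            if lab == "REM":
                if i == 0 or self.intervals[i - 1][2] != "NREM":
                    return False
        return True


def smooth_velocity(v: VelocityTrace, thresholds: StagingThresholds) -> VelocityTrace:
    """Gaussian-kernel smoothing (SD = bandwidth, 500 ms) with reflect padding."""
    if v.values.size == 0:
        raise ValueError("empty velocity trace")
    sigma = thresholds.velocity_smooth_bandwidth_ms / 1000.0 * v.sample_rate
    half = max(1, int(np.ceil(4.0 * sigma)))
    t = np.arange(-half, half + 1)
    kernel = np.exp(-(t ** 2) / (2.0 * sigma ** 2))
    kernel /= kernel.sum()
    padded = np.pad(v.values, half, mode="reflect") if v.values.size > half else \
        np.pad(v.values, half, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return VelocityTrace(values=np.maximum(smoothed, 0.0), sample_rate=v.sample_rate)


def _movement_seconds_per_epoch(v: VelocityTrace, n_epochs: int,
                                epoch_length_s: float, floor: float) -> np.ndarray:
    dt = 1.0 / v.sample_rate
    above = v.values > floor
    out = np.zeros(n_epochs)
    idx = (np.arange(v.values.size) * dt // epoch_length_s).astype(int)
    valid = idx < n_epochs
    np.add.at(out, idx[valid], above[valid] * dt)
    return out


def _sustained(sub_z: np.ndarray, z_thr: float, min_dur_s: float,
               sub_len_s: float = 1.0) -> np.ndarray:
    """Per epoch: does any run of supra-threshold 1-s subwindows last >= min_dur?"""
    need = int(np.ceil(min_dur_s / sub_len_s))
    hot = sub_z > z_thr
    n_epochs, n_sub = hot.shape
    if need <= 1:
        return hot.any(axis=1)
    out = np.zeros(n_epochs, dtype=bool)
    run = np.zeros(n_epochs, dtype=int)
    for j in range(n_sub):
        run = np.where(hot[:, j], run + 1, 0)
        out |= run >= need
    return out


def _provisional_quiet_wake(spectra: EpochSpectra, moved: np.ndarray,
                            thresholds: StagingThresholds) -> np.ndarray:
    """Bootstrap reference: the low-delta, low-power mode of still epochs.

    Quiet wakefulness is itself a staging output, so standardization starts
    from a provisional reference. Among non-movement, artifact-free epochs,
    quiet wake is the mode that is low in BOTH delta power (NREM's
    defining slow-wave feature — the strongest separator) and wideband
    power; a two-cluster split (seeded k-means on the standardized log of
    both) isolates it regardless of how much of the recording is sleep. A
    theta/delta filter then drops theta-dominant (REM-like) stragglers,
    whose delta can be as low as quiet wake's.
    """
    from sklearn.cluster import KMeans

    wb = spectra.band_power("wideband")
    delta = spectra.band_power("delta")
    ratio = spectra.theta_delta_ratio
    still = ~moved & ~spectra.artifact
    if still.sum() < 2:
        raise ValueError("too few still epochs to bootstrap a quiet-wake reference")
    feats = np.column_stack([
        np.log(np.maximum(delta[still], 1e-300)),
        np.log(np.maximum(wb[still], 1e-300)),
    ])
    sd = feats.std(axis=0)
    in_low = still.copy()
    if still.sum() >= 4 and np.all(sd > 1e-12):
        fz = (feats - feats.mean(axis=0)) / sd
        km = KMeans(n_clusters=2, random_state=0, n_init=10).fit(fz)
        low = int(np.argmin(km.cluster_centers_[:, 0]))
        in_low = np.zeros_like(still)
        in_low[np.nonzero(still)[0][km.labels_ == low]] = True
    ref = in_low & (ratio <= thresholds.theta_delta_rem)
    if ref.sum() < 2:  # degenerate split: fall back to the lower-power half
        cut = np.quantile(wb[still], 0.5)
        ref = still & (wb <= cut)
    return np.nonzero(ref)[0]


def _rule_pass(spectra: EpochSpectra, moved: np.ndarray,
               thresholds: StagingThresholds) -> list[str]:
    ratio = spectra.theta_delta_ratio
    nrem_wb = _sustained(spectra.sub_z, thresholds.wideband_nrem_z,
                         thresholds.wideband_nrem_min_dur_s)
    if thresholds.delta_nrem_z is not None:
        nrem_wb = nrem_wb | (spectra.band_z("delta") > thresholds.delta_nrem_z)
    labels: list[str] = []
    prev = "QW"  # REM impossible at t = 0
    for i in range(len(spectra)):
        if moved[i]:
            lab = "AW"
        elif ratio[i] > thresholds.theta_delta_rem and prev in ("NREM", "REM"):
            lab = "REM"
        elif nrem_wb[i]:
            lab = "NREM"
        else:
            lab = "QW"
        labels.append(lab)
        prev = lab
    return labels


def classify_epochs(spectra: EpochSpectra, velocity: VelocityTrace,
                    thresholds: StagingThresholds) -> Hypnogram:
    """Rule-based staging of every epoch; returns a REM-merged hypnogram.

    If the spectra are not yet standardized, a conservative quiet-wake
    reference is bootstrapped from the low-power tail of the non-movement
    epochs (the session-level quiet-wake standardization the analysis
    assumes). The reference is deliberately not re-estimated from the
    classified labels: misclassified sleep epochs leaking into the
    reference inflate its spread and bias the sustained-power criterion.
    """
    if velocity is None:
        raise ValueError("staging requires a velocity trace")
    n_epochs = len(spectra)
    el = spectra.epoch_length_s
    if velocity.duration + 1.0 / velocity.sample_rate < n_epochs * el:
        raise ValueError("velocity trace does not cover all epochs")
    sm = smooth_velocity(velocity, thresholds)
    move_s = _movement_seconds_per_epoch(sm, n_epochs, el,
                                         thresholds.movement_velocity_floor_cms)
    moved = move_s > thresholds.movement_aw_min_dur_s

    if spectra.sub_z is None:
        ref = _provisional_quiet_wake(spectra, moved, thresholds)
        standardize_to_quiet_wake(spectra, ref)
    labels = _rule_pass(spectra, moved, thresholds)
    hyp = Hypnogram.from_labels(labels, epoch_length_s=el)
    return merge_rem(hyp, thresholds)


def merge_rem(hypnogram: Hypnogram, thresholds: StagingThresholds) -> Hypnogram:
    """Merge REM runs separated by less than ``rem_merge_gap_s`` seconds.

    The intervening non-REM span is absorbed into the merged REM interval.
    Idempotent: a second application changes nothing.
    """
    gap = thresholds.rem_merge_gap_s
    ivs = hypnogram.intervals
    out: list[tuple[float, float, str]] = []
    i = 0
    while i < len(ivs):
        s, e, lab = ivs[i]
        if lab != "REM":
            out.append(ivs[i])
            i += 1
            continue
        end = e
        j = i + 1
        while j < len(ivs):
            # scan the non-REM run after the current REM end
            k = j
            gap_dur = 0.0
            while k < len(ivs) and ivs[k][2] != "REM":
                gap_dur += ivs[k][1] - ivs[k][0]
                k += 1
            if k < len(ivs) and gap_dur < gap:
                end = ivs[k][1]
                j = k + 1
            else:
                break
        out.append((s, end, "REM"))
        i = j
    return Hypnogram(intervals=out, epoch_length_s=hypnogram.epoch_length_s)


@dataclass
class SleepEpisode:
    """A sleep bout: NREM-initiated, brief-arousal-tolerant, > 5 min."""

    start: float
    end: float
    intervals: list[tuple[float, float, str]] = field(default_factory=list)
    n_transitions: int = 0
    n_brief_arousals: int = 0

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def sleep_time(self) -> float:
        return sum(e - s for s, e, lab in self.intervals if lab in SLEEP_STATES)

    @property
    def fragmentation_count(self) -> int:
        return self.n_transitions + self.n_brief_arousals


def find_sleep_episodes(hypnogram: Hypnogram,
                        min_duration_s: float = 300.0,
                        brief_arousal_max_s: float = 3.0) -> list[SleepEpisode]:
    """Maximal NREM-initiated sleep runs tolerating arousals under 3 s.

    An arousal lasting ``brief_arousal_max_s`` or more ends the episode
    (it is not counted inside it); episodes of ``min_duration_s`` or less
    are discarded. Transitions count label changes between consecutive
    sleep intervals (NREM<->REM switches, once per switch, including across
    a brief arousal).
    """
    ivs = hypnogram.intervals
    episodes: list[SleepEpisode] = []
    i = 0
    while i < len(ivs):
        if ivs[i][2] != "NREM":
            i += 1
            continue
        ep_ivs = [ivs[i]]
        last_sleep_label = "NREM"
        last_sleep_end = ivs[i][1]
        n_trans = 0
        n_brief = 0
        j = i + 1
        while j < len(ivs):
            s, e, lab = ivs[j]
            if lab in SLEEP_STATES:
                if lab != last_sleep_label:
                    n_trans += 1
                last_sleep_label = lab
                last_sleep_end = e
                ep_ivs.append(ivs[j])
                j += 1
            else:
                # wake run: sum consecutive wake intervals
                k = j
                wake_dur = 0.0
                while k < len(ivs) and ivs[k][2] in WAKE_STATES:
                    wake_dur += ivs[k][1] - ivs[k][0]
                    k += 1
                if wake_dur < brief_arousal_max_s and k < len(ivs):
                    n_brief += 1
                    ep_ivs.extend(ivs[j:k])
                    j = k
                else:
                    break
        ep = SleepEpisode(start=ep_ivs[0][0], end=last_sleep_end,
                          intervals=[iv for iv in ep_ivs if iv[0] < last_sleep_end],
                          n_transitions=n_trans, n_brief_arousals=n_brief)
        if ep.duration > min_duration_s:
            episodes.append(ep)
        i = j
    return episodes


@dataclass
class SFIResult:
    sfi: float  # fragmentation events per hour of episode sleep
    total_count: int
    total_sleep_hours: float
    per_episode: pd.DataFrame


def sleep_fragmentation_index(episodes: list[SleepEpisode],
                              hypnogram: Hypnogram | None = None) -> SFIResult:
    """SFI: NREM/REM transitions plus brief arousals, per hour of sleep.

    Raw counts are kept in the per-episode table; with no episodes the SFI
    is reported as 0 with a warning (no sleep to fragment).
    """
    rows = [
        {
            "start": ep.start, "end": ep.end, "duration_s": ep.duration,
            "sleep_time_s": ep.sleep_time, "n_transitions": ep.n_transitions,
            "n_brief_arousals": ep.n_brief_arousals, "count": ep.fragmentation_count,
        }
        for ep in episodes
    ]
    table = pd.DataFrame(rows, columns=["start", "end", "duration_s", "sleep_time_s",
                                        "n_transitions", "n_brief_arousals", "count"])
    if not episodes:
        warnings.warn("no sleep episodes found; SFI reported as 0", stacklevel=2)
        return SFIResult(sfi=0.0, total_count=0, total_sleep_hours=0.0, per_episode=table)
    total = int(table["count"].sum())
    hours = float(table["sleep_time_s"].sum()) / 3600.0
    sfi = total / hours if hours > 0 else 0.0
    return SFIResult(sfi=sfi, total_count=total, total_sleep_hours=hours, per_episode=table)


# ---------------------------------------------------------------------------
# random-forest automation


def epoch_features(rec: Recording, spectra: EpochSpectra, velocity: VelocityTrace,
                   thresholds: StagingThresholds) -> pd.DataFrame:
    """Per-epoch feature table for the supervised classifier.

    Band powers (log), theta/delta ratio, velocity mean/max and per-channel
    signal variance; sigma (10-15 Hz) power stands in for spindle presence.
    """
    n_epochs = len(spectra)
    el = spectra.epoch_length_s
    feats = {
        "log_theta": np.log(np.maximum(spectra.band_power("theta"), 1e-300)),
        "log_delta": np.log(np.maximum(spectra.band_power("delta"), 1e-300)),
        "log_sigma": np.log(np.maximum(spectra.band_power("sigma"), 1e-300)),
        "log_wideband": np.log(np.maximum(spectra.band_power("wideband"), 1e-300)),
        "theta_delta_ratio": spectra.theta_delta_ratio,
    }
    sm = smooth_velocity(velocity, thresholds)
    vmean = np.zeros(n_epochs)
    vmax = np.zeros(n_epochs)
    idx = (sm.times // el).astype(int)
    for i in range(n_epochs):
        seg = sm.values[idx == i]
        if seg.size:
            vmean[i], vmax[i] = seg.mean(), seg.max()
    feats["velocity_mean"] = vmean
    feats["velocity_max"] = vmax
    nper = int(round(el * rec.sample_rate))
    for ch, role in enumerate(rec.channel_roles):
        x = rec.samples[ch, : n_epochs * nper].reshape(n_epochs, nper)
        feats[f"log_var_{role}"] = np.log(np.maximum(x.var(axis=1), 1e-300))
    return pd.DataFrame(feats)


def train_state_classifier(features: pd.DataFrame, labels: Sequence[str], seed: int):
    """Fit a random forest on epoch features; all four states must be present."""
    from sklearn.ensemble import RandomForestClassifier

    labels = list(labels)
    missing = [s for s in STATES if s not in labels]
    if missing:
        raise ValueError(f"training labels lack state(s): {missing}")
    clf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    clf.fit(features.to_numpy(), labels)
    return clf


def apply_state_classifier(clf, features: pd.DataFrame,
                           epoch_length_s: float = EPOCH_LENGTH_S) -> Hypnogram:
    """Predict epoch labels and enforce the REM-entry rule sequentially.

    A predicted REM epoch whose running prior state is not NREM/REM is
    reassigned to the most probable non-REM class.
    """
    proba = clf.predict_proba(features.to_numpy())
    classes = list(clf.classes_)
    labels: list[str] = []
    prev = "QW"
    for row in proba:
        order = [classes[k] for k in np.argsort(row)[::-1]]
        lab = order[0]
        if lab == "REM" and prev not in ("NREM", "REM"):
            lab = next(c for c in order if c != "REM")
        labels.append(lab)
        prev = lab
    return Hypnogram.from_labels(labels, epoch_length_s=epoch_length_s)
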