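"""Synthetic 4-channel rodent EEG with ground truth.

The generative model mirrors the statistical structure the analysis assumes:

* behavioral states (AW, QW, NREM, REM) follow a first-order Markov chain on
  the 10-s scoring grid, with REM reachable only from NREM;
* each state imposes a spectral profile — a 1/f^alpha Gaussian background
  with a per-state gain plus narrowband oscillations (REM: strong 5-10 Hz
  theta; NREM: elevated 0.5-4 Hz delta and higher wideband power);
* interictal spikes are state-conditional Poisson events, injected as
  synchronized biphasic transients (<= 75 ms) whose peaks reach a target
  z-score on 3 or 4 channels;
* cable artifacts are monophasic, latency-jittered transients across
  channels (so they fail the biphasic spike definition at the template
  level);
* movement bouts drive a 10-Hz velocity trace during active wakefulness;
* optional ictal segments are broadband amplitude surges.

Everything is driven by one integer seed; identical configs and seeds give
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .config import CHANNEL_ROLES, EPOCH_LENGTH_S, STATES, GeneratorConfig
from .io_formats import Recording, VelocityTrace

__all__ = [
    "GroundTruth",
    "generate_ground_truth",
    "generate_recording",
    "inject_iis",
    "biphasic_pulse",
    "pink_noise",
]


@dataclass
class GroundTruth:
    """Generator-side truth: state intervals, spike times/masks, artifacts, seizures."""

    state_intervals: list[tuple[float, float, str]]
    iis_times: list[tuple[float, tuple[bool, bool, bool, bool]]]
    artifact_times: list[float] = field(default_factory=list)
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return self.state_intervals[-1][1] if self.state_intervals else 0.0

    def labels_on_grid(self, epoch_length_s: float = EPOCH_LENGTH_S) -> list[str]:
        """State label of each full epoch (state at the epoch midpoint)."""
        n = int(self.duration // epoch_length_s)
        labels = []
        it = iter(self.state_intervals)
        cur = next(it)
        for i in range(n):
            t = (i + 0.5) * epoch_length_s
            while t >= cur[1]:
                cur = next(it)
            labels.append(cur[2])
        return labels

    def state_at(self, t: float) -> str:
        for s, e, lab in self.state_intervals:
            if s <= t < e:
                return lab
        raise ValueError(f"time {t} outside ground-truth span")

    def to_json(self, path) -> None:
        obj = {
            "state_intervals": [[s, e, lab] for s, e, lab in self.state_intervals],
            "iis_times": [[t, list(map(bool, m))] for t, m in self.iis_times],
            "artifact_times": list(self.artifact_times),
            "seizure_intervals": [list(x) for x in self.seizure_intervals],
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            state_intervals=[(s, e, lab) for s, e, lab in obj["state_intervals"]],
            iis_times=[(t, tuple(m)) for t, m in obj["iis_times"]],
            artifact_times=obj.get("artifact_times", []),
            seizure_intervals=[tuple(x) for x in obj.get("seizure_intervals", [])],
        )


# ---------------------------------------------------------------------------
# building blocks


def _shaped_noise(n: int, shape: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with the given one-sided amplitude shape.

    Drawn directly in the frequency domain (one inverse FFT), which is
    statistically identical to shaping white noise but twice as fast.
    """
    m = n // 2 + 1
    re = rng.standard_normal(m)
    im = rng.standard_normal(m)
    spec = (re + 1j * im) * shape
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = re[-1] * shape[-1]
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(n: int, alpha: float, rng: np.random.Generator, sample_rate: float,
               f_floor: float = 0.5) -> np.ndarray:
    """Unit-variance 1/f^alpha Gaussian noise via spectral shaping.

    The amplitude spectrum follows f^(-alpha/2), flattened below ``f_floor``
    so the DC end stays bounded (the acquisition is highpassed at 0.5 Hz
    anyway).
    """
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shape = np.maximum(f, f_floor) ** (-alpha / 2.0)
    return _shaped_noise(n, shape, rng)


def _narrowband_noise(n: int, center_hz: float, bandwidth_hz: float,
                      rng: np.random.Generator, sample_rate: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a Gaussian spectral envelope."""
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    env = np.exp(-0.5 * ((f - center_hz) / max(bandwidth_hz / 2.0, 1e-6)) ** 2)
    return _shaped_noise(n, env, rng)


def biphasic_pulse(width_ms: float, sample_rate: float) -> np.ndarray:
    """Biphasic Gaussian-derivative pulse, positive and negative peaks at +/-1.

    ``width_ms`` is the total support (+/- 3 sigma); the two extrema sit at
    -sigma and +sigma. The shape is a generator-side choice — the analysis
    only constrains spike duration and amplitude, not waveform.
    """
    sigma_s = (width_ms / 1000.0) / 6.0
    half = int(np.ceil(3.0 * sigma_s * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    g = -t * np.exp(-(t ** 2) / (2.0 * sigma_s ** 2))
    peak = sigma_s * np.exp(-0.5)
    return g / peak


def _artifact_pulse(sample_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Monophasic fast-rise / exponential-decay transient (cable scratch)."""
    rise_s, tau_s, total_s = 0.004, 0.015, 0.12
    n = int(total_s * sample_rate)
    t = np.arange(n) / sample_rate
    w = np.where(t < rise_s, t / rise_s, np.exp(-(t - rise_s) / tau_s))
    return w * (1.0 if rng.random() < 0.5 else -1.0)


def _local_sd(x: np.ndarray, idx: int, half_win: int) -> float:
    lo = max(0, idx - half_win)
    hi = min(x.size, idx + half_win)
    return float(np.std(x[lo:hi]))


def inject_iis(rec: Recording, times: Sequence, amplitude_z: float,
               width_ms: float) -> Recording:
    """Return a copy of ``rec`` with biphasic transients added at ``times``.

    ``times`` holds seconds, or ``(seconds, channel_mask)`` pairs; on each
    masked channel the pulse is scaled so its peak sits ``amplitude_z`` local
    baseline standard deviations above (and below) the signal, estimated in
    a +/-1 s window around the event.
    """
    if width_ms > 75.0:
        raise ValueError(f"IIS width must be <= 75 ms, got {width_ms}")
    out = rec.samples.copy()
    fs = rec.sample_rate
    pulse = biphasic_pulse(width_ms, fs)
    half = pulse.size // 2
    win = int(fs)  # 1-s local baseline window
    for item in times:
        if isinstance(item, (tuple, list)):
            t, mask = item
        else:
            t, mask = item, (True,) * 4
        idx = int(round(t * fs))
        if idx - half < 0 or idx + half + 1 > rec.n_samples:
            raise ValueError(f"event at {t} s does not fit inside the recording")
        for ch in range(out.shape[0]):
            if mask[ch]:
                sd = _local_sd(rec.samples[ch], idx, win)
                out[ch, idx - half : idx + half + 1] += amplitude_z * sd * pulse
    return Recording(samples=out, sample_rate=fs, start_time=rec.start_time)


# ---------------------------------------------------------------------------
# ground truth


def _simulate_state_chain(cfg: GeneratorConfig, rng: np.random.Generator) -> list[str]:
    n_epochs = int(cfg.duration_s // EPOCH_LENGTH_S)
    P = np.asarray(cfg.state_transition_matrix, dtype=float)
    cum = np.cumsum(P, axis=1)
    state = STATES.index(cfg.initial_state)
    labels = []
    u = rng.random(n_epochs)
    for i in range(n_epochs):
        labels.append(STATES[state])
        state = int(np.searchsorted(cum[state], u[i], side="right"))
        state = min(state, 3)
    return labels


def _labels_to_intervals(labels: Sequence[str],
                         epoch_length_s: float = EPOCH_LENGTH_S) -> list[tuple[float, float, str]]:
    intervals: list[tuple[float, float, str]] = []
    for i, lab in enumerate(labels):
        t0, t1 = i * epoch_length_s, (i + 1) * epoch_length_s
        if intervals and intervals[-1][2] == lab:
            intervals[-1] = (intervals[-1][0], t1, lab)
        else:
            intervals.append((t0, t1, lab))
    return intervals


def _sample_event_times(intervals, rates_per_hour, duration, rng,
                        min_sep_s: float = 0.5, margin_s: float = 0.3) -> list[float]:
    """State-conditional Poisson times, thinned to a minimum separation."""
    times: list[float] = []
    for s, e, lab in intervals:
        rate = rates_per_hour.get(lab, 0.0) / 3600.0
        if rate <= 0:
            continue
        n = rng.poisson(rate * (e - s))
        times.extend(np.sort(s + rng.random(n) * (e - s)))
    times = sorted(t for t in times if margin_s <= t <= duration - margin_s)
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_sep_s:
            kept.append(t)
    return kept


def generate_ground_truth(cfg: GeneratorConfig,
                          rng: np.random.Generator | None = None) -> GroundTruth:
    """Simulate states and event times only (no signal synthesis)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    labels = _simulate_state_chain(cfg, rng)
    intervals = _labels_to_intervals(labels)
    if not intervals:
        raise ValueError("duration shorter than one epoch")

    iis_raw = _sample_event_times(intervals, cfg.iis_rate_per_hour, cfg.duration_s, rng)
    iis_times: list[tuple[float, tuple[bool, bool, bool, bool]]] = []
    for t in iis_raw:
        mask = [True] * 4
        if rng.random() < cfg.iis_channel_subset_prob:
            mask[rng.integers(4)] = False
        iis_times.append((t, tuple(mask)))

    n_art = rng.poisson(cfg.artifact_rate_per_hour * cfg.duration_s / 3600.0)
    artifact_times = sorted(0.5 + rng.random(n_art) * (cfg.duration_s - 1.0))
    # keep artifacts clear of true spikes so truth labels stay unambiguous
    artifact_times = [
        t for t in artifact_times
        if not any(abs(t - it) < 0.5 for it, _ in iis_times)
    ]

    seiz = [(float(s[0]), float(s[0]) + float(s[1])) for s in cfg.seizure_spec]
    return GroundTruth(
        state_intervals=intervals,
        iis_times=iis_times,
        artifact_times=artifact_times,
        seizure_intervals=seiz,
    )


# ---------------------------------------------------------------------------
# signal + velocity synthesis


def _state_sample_masks(truth: GroundTruth, n: int, fs: float) -> dict[str, np.ndarray]:
    masks = {s: np.zeros(n, dtype=bool) for s in STATES}
    for s, e, lab in truth.state_intervals:
        masks[lab][int(s * fs) : int(e * fs)] = True
    return masks


def _synthesize_velocity(truth: GroundTruth, cfg: GeneratorConfig,
                         rng: np.random.Generator) -> VelocityTrace:
    fs = cfg.velocity_rate
    n = int(round(truth.duration * fs))
    bp = cfg.movement_bout_params
    v = np.abs(rng.standard_normal(n)) * bp.rest_jitter_cms

    # movement bouts inside AW intervals: alternating on/off runs, offs kept
    # short (< 3 s) so every AW epoch carries supra-threshold movement
    for s, e, lab in truth.state_intervals:
        if lab != "AW":
            continue
        i0, i1 = int(s * fs), int(e * fs)
        t = i0
        moving = True
        while t < i1:
            if moving:
                run = max(1, int(rng.exponential(bp.bout_duration_mean_s) * fs))
                seg = slice(t, min(t + run, i1))
                amp = bp.peak_velocity_cms * (0.4 + 0.6 * rng.random())
                raw = np.abs(rng.standard_normal(seg.stop - seg.start))
                v[seg] = 1.5 + amp * raw / max(raw.max(), 1e-9)
            else:
                run = max(1, int(min(rng.exponential(1.0), 2.5) * fs))
                t_end = min(t + run, i1)
                run = t_end - t
            t += run if not moving else (seg.stop - seg.start)
            moving = not moving
    return VelocityTrace(values=v, sample_rate=fs)


def generate_recording(cfg: GeneratorConfig
                       ) -> tuple[Recording, VelocityTrace, GroundTruth]:
    """Synthesize a full session: EEG, velocity trace and ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = generate_ground_truth(cfg, rng)
    fs = cfg.sample_rate
    n = int(round(cfg.duration_s * fs))
    n_used = int(truth.duration * fs)  # whole epochs only
    masks = _state_sample_masks(truth, n, fs)

    gain = np.ones(n)
    for state, spec in cfg.state_spectra.items():
        gain[masks[state]] = spec.gain

    def _components(state: str, spec) -> list:
        comps = list(spec.components)
        if state == "NREM" and cfg.nrem_spindles:
            from .config import OscComponent
            comps.append(OscComponent(12.5, 2.0, 1.0))
        return comps

    samples = np.empty((4, n))
    for ch in range(4):
        x = pink_noise(n, cfg.background_exponent, rng, fs)
        x *= cfg.background_scale_uv * gain
        # narrowband components synthesized per state interval (hard-gated at
        # epoch boundaries either way; keeps the FFTs small)
        for s, e, lab in truth.state_intervals:
            spec = cfg.state_spectra.get(lab)
            if spec is None:
                continue
            i0, i1 = int(s * fs), int(e * fs)
            for comp in _components(lab, spec):
                nb = _narrowband_noise(i1 - i0, comp.center_hz, comp.bandwidth_hz,
                                       rng, fs)
                amp = np.sqrt(comp.rel_power) * spec.gain * cfg.background_scale_uv
                x[i0:i1] += amp * nb
        samples[ch] = x
    if n_used < n:
        samples = samples[:, :n_used]
    rec = Recording(samples=samples, sample_rate=fs)

    # ictal segments: broadband amplitude surge with 0.5-s cosine ramps
    for spec in cfg.seizure_spec:
        s0, dur, amp = float(spec[0]), float(spec[1]), float(spec[2])
        chans = list(spec[3]) if len(spec) > 3 else list(range(4))
        i0, i1 = int(s0 * fs), min(int((s0 + dur) * fs), rec.n_samples)
        m = i1 - i0
        if m <= 0:
            continue
        ramp = np.ones(m)
        r = min(int(0.5 * fs), m // 2)
        if r > 0:
            edge = 0.5 * (1 - np.cos(np.linspace(0, np.pi, r)))
            ramp[:r], ramp[-r:] = edge, edge[::-1]
        for ch in chans:
            sd = _local_sd(rec.samples[ch], i0, int(2 * fs))
            rec.samples[ch, i0:i1] += amp * sd * ramp * rng.standard_normal(m)

    if truth.iis_times:
        rec = inject_iis(rec, truth.iis_times, cfg.iis_amplitude_z, cfg.iis_width_ms)

    # cable artifacts: monophasic, latency-jittered across channels
    for t in truth.artifact_times:
        base = _artifact_pulse(fs, rng)
        for ch in range(4):
            jit = rng.uniform(-0.025, 0.025)
            amp_z = rng.uniform(8.0, 14.0)
            idx = int(round((t + jit) * fs))
            if idx < 0 or idx + base.size > rec.n_samples:
                continue
            sd = _local_sd(rec.samples[ch], idx, int(fs))
            rec.samples[ch, idx : idx + base.size] += amp_z * sd * base

    vel = _synthesize_velocity(truth, cfg, rng)
    return rec, vel, truth


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(np.asarray(P, dtype=float).T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()
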