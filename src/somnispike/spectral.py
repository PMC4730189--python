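"""Epoch-wise FFT spectra, quiet-wake z-standardization, Morlet wavelets.

The quantification pipeline: downsample to 1000 Hz, cut into 10-s epochs,
single Hann-taper FFT power per epoch, then express power as a z-score per
frequency bin against the mean/SD over quiet-wakefulness epochs of the same
session. Band summaries use theta 5-10 Hz, delta 0.5-4 Hz and wideband
0.5-200 Hz; time-frequency maps use a 7-cycle complex Morlet wavelet with
the same quiet-wake standardization per frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps

from .config import AnalysisConfig
from .io_formats import Recording

__all__ = [
    "preprocess",
    "EpochSpectra",
    "EpochSpectrum",
    "epoch_psd",
    "standardize_to_quiet_wake",
    "peak_theta_distribution",
    "wavelet_tfr",
    "morlet_kernel",
]


def preprocess(rec: Recording, cfg: AnalysisConfig) -> Recording:
    """Anti-alias filter and downsample to ``cfg.downsample_rate``.

    Pass-through when the rate already matches; upsampling is refused.
    """
    if rec.sample_rate < cfg.downsample_rate:
        raise ValueError(
            f"cannot upsample {rec.sample_rate} Hz to {cfg.downsample_rate} Hz"
        )
    if rec.sample_rate == cfg.downsample_rate:
        return rec
    frac = Fraction(cfg.downsample_rate / rec.sample_rate).limit_denominator(1000)
    out = sps.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=1)
    return Recording(samples=out, sample_rate=cfg.downsample_rate,
                     start_time=rec.start_time)


@dataclass
class EpochSpectrum:
    """Single-epoch spectrum view (see :class:`EpochSpectra`)."""

    epoch_index: int
    freqs: np.ndarray
    power_raw: np.ndarray
    power_z: Optional[np.ndarray]
    band_power: dict[str, float]
    theta_delta_ratio: float


@dataclass
class EpochSpectra:
    """Per-epoch Hann-taper power spectra for one channel, as arrays.

    ``power_raw`` is a density (uV^2/Hz) matrix, epochs by frequency bins;
    ``power_z`` is filled by :func:`standardize_to_quiet_wake`.
    ``sub_logpower`` holds wideband log-power in 1-s subwindows (epochs by
    10), used for the sustained-power staging criterion; ``artifact`` flags
    epochs contaminated by large non-spike excursions — those are excluded
    from reference statistics and spectral summaries.
    """

    freqs: np.ndarray
    power_raw: np.ndarray
    epoch_length_s: float
    cfg: AnalysisConfig
    channel_role: str
    power_z: Optional[np.ndarray] = None
    sub_logpower: Optional[np.ndarray] = None
    sub_z: Optional[np.ndarray] = None
    artifact: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    _band_z: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return self.power_raw.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.power_raw.shape[0]

    def _band_idx(self, band: tuple[float, float]) -> np.ndarray:
        lo, hi = band
        return (self.freqs >= lo) & (self.freqs <= hi)

    def band_power(self, name: str) -> np.ndarray:
        """Integrated power (trapezoid over density) in a named band."""
        band = getattr(self.cfg, name if name.endswith("band") else f"{name}_band")
        idx = self._band_idx(band)
        return np.trapezoid(self.power_raw[:, idx], self.freqs[idx], axis=1)

    @property
    def theta_delta_ratio(self) -> np.ndarray:
        delta = self.band_power("delta")
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(delta > 0, self.band_power("theta") / delta, np.inf)

    def band_z(self, name: str) -> np.ndarray:
        if name not in self._band_z:
            raise ValueError(f"band z for {name!r} requires standardization first")
        return self._band_z[name]

    def get(self, i: int) -> EpochSpectrum:
        return EpochSpectrum(
            epoch_index=i,
            freqs=self.freqs,
            power_raw=self.power_raw[i],
            power_z=None if self.power_z is None else self.power_z[i],
            band_power={
                "theta": float(self.band_power("theta")[i]),
                "delta": float(self.band_power("delta")[i]),
                "wideband": float(self.band_power("wideband")[i]),
            },
            theta_delta_ratio=float(self.theta_delta_ratio[i]),
        )


def _hann_psd(segments: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Single Hann-taper one-sided power density per row of ``segments``."""
    n = segments.shape[-1]
    w = sps.get_window("hann", n)
    x = segments - segments.mean(axis=-1, keepdims=True)
    X = np.fft.rfft(x * w, axis=-1)
    scale = 2.0 / (fs * np.sum(w ** 2))
    p = (np.abs(X) ** 2) * scale
    p[..., 0] /= 2.0
    if n % 2 == 0:
        p[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, p


def flag_artifact_epochs(rec: Recording, cfg: AnalysisConfig,
                         iis_times: Sequence[float] = (),
                         artifact_times: Sequence[float] = ()) -> np.ndarray:
    """Epochs contaminated by large excursions outside known spike times.

    A sample is an excursion when its robust z (median/MAD) exceeds
    ``cfg.artifact_z`` on any channel; samples within 100 ms of a known
    spike are exempt. Epochs overlapping declared artifact times are
    flagged regardless.
    """
    fs = rec.sample_rate
    nper = int(round(cfg.epoch_length_s * fs))
    n_epochs = rec.n_samples // nper
    flags = np.zeros(n_epochs, dtype=bool)
    exempt = np.zeros(rec.n_samples, dtype=bool)
    pad = int(0.1 * fs)
    for t in iis_times:
        i = int(round(t * fs))
        exempt[max(0, i - pad) : i + pad] = True
    for ch in range(rec.samples.shape[0]):
        x = rec.samples[ch]
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * 1.4826
        if mad == 0:
            continue
        bad = (np.abs(x - med) / mad > cfg.artifact_z) & ~exempt
        hits = np.unique(np.nonzero(bad)[0] // nper)
        flags[hits[hits < n_epochs]] = True
    for t in artifact_times:
        e = int(t // cfg.epoch_length_s)
        if 0 <= e < n_epochs:
            flags[e] = True
    return flags


def epoch_psd(rec: Recording, cfg: AnalysisConfig, channel_role: str = "FC",
              iis_times: Sequence[float] = (),
              artifact_times: Sequence[float] = ()) -> EpochSpectra:
    """Hann-taper FFT power per 10-s epoch on one channel.

    The epoch grid is anchored at t = 0; the last partial epoch is dropped.
    Artifact-contaminated epochs are flagged (not removed) so the hypnogram
    grid stays intact while spectral statistics can exclude them.
    """
    if rec.sample_rate != cfg.downsample_rate:
        raise ValueError("recording must be preprocessed to the analysis rate first")
    fs = rec.sample_rate
    nper = int(round(cfg.epoch_length_s * fs))
    n_epochs = rec.n_samples // nper
    if n_epochs == 0:
        raise ValueError("recording shorter than one epoch")
    x = rec.channel(channel_role)[: n_epochs * nper].reshape(n_epochs, nper)
    freqs, power = _hann_psd(x, fs)

    # 1-s subwindows for the sustained-wideband staging criterion
    nsub = int(round(fs))
    n_per_epoch = nper // nsub
    sub = x[:, : n_per_epoch * nsub].reshape(n_epochs * n_per_epoch, nsub)
    sf, sp = _hann_psd(sub, fs)
    wb = cfg.wideband
    idx = (sf >= wb[0]) & (sf <= wb[1])
    sub_power = np.trapezoid(sp[:, idx], sf[idx], axis=1)
    sub_logpower = np.log(np.maximum(sub_power, 1e-300)).reshape(n_epochs, n_per_epoch)

    artifact = flag_artifact_epochs(rec, cfg, iis_times, artifact_times)
    return EpochSpectra(
        freqs=freqs, power_raw=power, epoch_length_s=cfg.epoch_length_s,
        cfg=cfg, channel_role=channel_role, sub_logpower=sub_logpower,
        artifact=artifact[:n_epochs],
    )


def standardize_to_quiet_wake(spectra: EpochSpectra,
                              quiet_wake_epoch_ids: Sequence[int]) -> EpochSpectra:
    """Z-score power per frequency bin against quiet-wake epochs (in place).

    Also standardizes the 1-s wideband log-power subwindows and band powers
    against the same reference set. At least two artifact-free reference
    epochs are required; a zero-variance bin signals a degenerate reference.
    """
    ids = np.asarray(sorted(set(int(i) for i in quiet_wake_epoch_ids)), dtype=int)
    if ids.size and spectra.artifact.size:
        ids = ids[~spectra.artifact[ids]]
    if ids.size < 2:
        raise ValueError("need at least 2 artifact-free quiet-wake reference epochs")
    ref = spectra.power_raw[ids]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("zero variance in a frequency bin of the quiet-wake reference")
    spectra.power_z = (spectra.power_raw - mu) / sd

    if spectra.sub_logpower is not None:
        sref = spectra.sub_logpower[ids].ravel()
        smu, ssd = sref.mean(), sref.std(ddof=0)
        if ssd == 0:
            raise ValueError("zero variance in quiet-wake subwindow power")
        spectra.sub_z = (spectra.sub_logpower - smu) / ssd

    for name in ("theta", "delta", "sigma", "wideband"):
        bp = spectra.band_power(name)
        bref = bp[ids]
        bsd = bref.std(ddof=0)
        spectra._band_z[name] = (bp - bref.mean()) / bsd if bsd > 0 else np.zeros_like(bp)
    return spectra


def peak_theta_distribution(spectra: EpochSpectra, rem_epoch_ids: Sequence[int],
                            cfg: AnalysisConfig | None = None) -> np.ndarray:
    """Peak theta frequency (largest 5-10 Hz local maximum) per REM epoch.

    Epochs whose band-restricted spectrum has no interior local maximum fall
    back to the band argmax.
    """
    cfg = cfg or spectra.cfg
    ids = np.asarray(list(rem_epoch_ids), dtype=int)
    if spectra.artifact.size:
        ids = ids[~spectra.artifact[ids]]
    if ids.size == 0:
        raise ValueError("no (artifact-free) REM epochs")
    lo, hi = cfg.theta_band
    bidx = np.nonzero((spectra.freqs >= lo) & (spectra.freqs <= hi))[0]
    peaks = np.empty(ids.size)
    for j, i in enumerate(ids):
        p = spectra.power_raw[i, bidx]
        interior = np.nonzero((p[1:-1] > p[:-2]) & (p[1:-1] > p[2:]))[0] + 1
        k = interior[np.argmax(p[interior])] if interior.size else int(np.argmax(p))
        peaks[j] = spectra.freqs[bidx[k]]
    return peaks


# ---------------------------------------------------------------------------
# Morlet wavelets


def morlet_kernel(freq_hz: float, sample_rate: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, Gaussian SD sigma_t = n_cycles / (2 pi f),
    truncated at +/-4 sigma_t and L2-normalized."""
    sigma_t = n_cycles / (2.0 * np.pi * freq_hz)
    half = int(np.ceil(4.0 * sigma_t * sample_rate))
    t = np.arange(-half, half + 1) / sample_rate
    k = np.exp(2j * np.pi * freq_hz * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return k / np.linalg.norm(k)


@dataclass
class TimeFrequency:
    """Wavelet power map: frequencies by time samples."""

    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray  # raw, uV^2-scaled (arbitrary common factor)
    power_z: Optional[np.ndarray] = None


def wavelet_tfr(rec: Recording, cfg: AnalysisConfig, channel_role: str = "FC",
                quiet_wake_mask: np.ndarray | None = None) -> TimeFrequency:
    """7-cycle complex-Morlet time-frequency power, z per frequency.

    ``quiet_wake_mask`` is a boolean per-sample mask of quiet wakefulness;
    when given, power at each frequency is z-scored against its mean/SD over
    quiet-wake samples.
    """
    fs = rec.sample_rate
    if cfg.wavelet_fmax >= fs / 2:
        raise ValueError(f"wavelet fmax {cfg.wavelet_fmax} exceeds Nyquist {fs / 2}")
    n_oct = np.log2(cfg.wavelet_fmax / cfg.wavelet_fmin)
    n_f = int(np.floor(n_oct * cfg.wavelet_per_octave)) + 1
    freqs = cfg.wavelet_fmin * 2.0 ** (np.arange(n_f) / cfg.wavelet_per_octave)
    x = rec.channel(channel_role)
    power = np.empty((n_f, x.size))
    for i, f in enumerate(freqs):
        k = morlet_kernel(f, fs, cfg.wavelet_cycles)
        conv = sps.fftconvolve(x, k, mode="same")
        power[i] = np.abs(conv) ** 2
    tf = TimeFrequency(freqs=freqs, times=rec.times, power=power)
    if quiet_wake_mask is not None:
        m = np.asarray(quiet_wake_mask, dtype=bool)
        if m.size != x.size:
            raise ValueError("quiet-wake mask length must match the recording")
        if m.sum() < 2:
            raise ValueError("quiet-wake reference too small")
        mu = power[:, m].mean(axis=1, keepdims=True)
        sd = power[:, m].std(axis=1, ddof=0, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("zero variance in quiet-wake wavelet power")
        tf.power_z = (power - mu) / sd
    return tf
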