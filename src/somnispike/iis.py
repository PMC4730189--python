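"""Interictal spike (IIS) detection.

An IIS is a transient (<= 75 ms threshold-crossing span), large (7 z above
and below the per-channel baseline mean) event appearing synchronously on
the 4 recording channels; events on exactly 3 channels are kept as
"IIS-like". Detection proceeds in three stages:

1. per-channel robust z-scoring against baseline (artifact-free NREM + QW)
   and excursion detection with the amplitude/duration rules;
2. cross-channel grouping within a coincidence window (>= 3 channels) and
   a 200-ms refractory merge, yielding candidates with 200-ms waveform
   snippets (-50/+150 ms around the first peak);
3. template refinement: PCA (10 components) + k-means over the snippets,
   clusters labeled spike vs artifact by re-applying the amplitude /
   duration / biphasic / synchrony definition to each cluster centroid,
   then iterative re-screening of events by normalized correlation against
   the spike templates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .config import EPOCH_LENGTH_S, IISDetectionConfig
from .io_formats import Recording

__all__ = [
    "IISEvent",
    "channel_zscore",
    "baseline_mask_from_epochs",
    "detect_candidates",
    "refine_templates",
    "spike_triggered_average",
    "detect_iis",
]

logger = logging.getLogger(__name__)


@dataclass
class IISEvent:
    """One detected transient across channels (times in seconds)."""

    onset: float
    per_channel_peaks: list[Optional[tuple[float, float]]]  # (time, z) or None
    n_channels: int
    waveform: np.ndarray  # (4, snippet samples), z units
    spans_ms: list[Optional[float]] = field(default_factory=lambda: [None] * 4)
    cluster_id: int = -1
    label: str = "candidate"  # candidate | IIS | IIS-like | artifact

    @property
    def channel_mask(self) -> tuple[bool, bool, bool, bool]:
        return tuple(p is not None for p in self.per_channel_peaks)

    @property
    def peak_z(self) -> float:
        return max(abs(p[1]) for p in self.per_channel_peaks if p is not None)


def baseline_mask_from_epochs(n_samples: int, sample_rate: float,
                              epoch_ids: Sequence[int],
                              epoch_length_s: float = EPOCH_LENGTH_S) -> np.ndarray:
    mask = np.zeros(n_samples, dtype=bool)
    nper = int(round(epoch_length_s * sample_rate))
    for e in epoch_ids:
        mask[e * nper : (e + 1) * nper] = True
    return mask


def channel_zscore(rec: Recording, baseline: np.ndarray | Sequence[int]) -> Recording:
    """Per-channel robust z against baseline (median, MAD * 1.4826).

    ``baseline`` is a boolean sample mask or a list of 10-s epoch indices.
    """
    b = np.asarray(baseline)
    if b.dtype != bool:
        b = baseline_mask_from_epochs(rec.n_samples, rec.sample_rate, b)
    if b.sum() == 0:
        raise ValueError("empty baseline")
    z = np.empty_like(rec.samples)
    for ch in range(rec.samples.shape[0]):
        ref = rec.samples[ch, b]
        med = np.median(ref)
        sd = np.median(np.abs(ref - med)) * 1.4826
        if sd == 0:
            raise ValueError(
                f"zero baseline SD on channel {rec.channel_roles[ch]} (constant signal?)"
            )
        logger.debug("baseline %s: median=%.3f uV, robust SD=%.3f uV",
                     rec.channel_roles[ch], med, sd)
        z[ch] = (rec.samples[ch] - med) / sd
    return Recording(samples=z, sample_rate=rec.sample_rate, start_time=rec.start_time)


def _excursions(z: np.ndarray, fs: float, z_thr: float, max_dur_ms: float):
    """Supra-threshold excursions on one channel.

    Runs of |z| >= threshold separated by less than the maximum duration are
    one excursion (the two phases of a biphasic transient); excursions whose
    first-to-last crossing span exceeds the maximum duration are rejected —
    that is the transience rule.
    """
    hot = np.abs(z) >= z_thr
    if not hot.any():
        return []
    d = np.diff(hot.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if hot[0]:
        starts = np.r_[0, starts]
    if hot[-1]:
        ends = np.r_[ends, hot.size]
    gap_max = int(round(max_dur_ms / 1000.0 * fs))
    out = []
    cs, ce = starts[0], ends[0]
    groups = []
    for s, e in zip(starts[1:], ends[1:]):
        if s - ce < gap_max:
            ce = e
        else:
            groups.append((cs, ce))
            cs, ce = s, e
    groups.append((cs, ce))
    for s, e in groups:
        span_ms = (e - s) / fs * 1000.0
        if span_ms > max_dur_ms:
            continue
        seg = z[s:e]
        k = int(np.argmax(np.abs(seg)))
        out.append({"start": s, "end": e, "peak_idx": s + k,
                    "peak_z": float(seg[k]), "span_ms": span_ms})
    return out


def detect_candidates(zrec: Recording, cfg: IISDetectionConfig) -> list[IISEvent]:
    """Amplitude/duration/synchrony candidates from a z-scored recording.

    Per-channel excursions are grouped when their peaks fall within the
    coincidence window of the group's earliest peak; groups on >= 3
    channels survive. Groups closer than the refractory window are merged
    (multiphasic spikes count once). Snippets span -50/+150 ms around the
    earliest peak; events too close to the edges to extract one are dropped.
    """
    cfg.validate()
    fs = zrec.sample_rate
    peaks = []  # (peak_idx, channel, excursion dict)
    for ch in range(zrec.samples.shape[0]):
        for exc in _excursions(zrec.samples[ch], fs, cfg.z_threshold, cfg.max_duration_ms):
            peaks.append((exc["peak_idx"], ch, exc))
    peaks.sort(key=lambda p: p[0])

    win = cfg.coincidence_window_ms / 1000.0 * fs
    groups: list[list] = []
    for p in peaks:
        if groups and p[0] - groups[-1][0][0] <= win:
            groups[-1].append(p)
        else:
            groups.append([p])

    # refractory merge of neighboring groups
    refr = cfg.refractory_ms / 1000.0 * fs
    merged: list[list] = []
    for g in groups:
        if merged and g[0][0] - merged[-1][-1][0] <= refr:
            merged[-1].extend(g)
        else:
            merged.append(g)

    pre = int(round(cfg.waveform_pre_ms / 1000.0 * fs))
    post = int(round(cfg.waveform_post_ms / 1000.0 * fs))
    events: list[IISEvent] = []
    for g in merged:
        per_ch: list[Optional[tuple[float, float]]] = [None] * 4
        spans: list[Optional[float]] = [None] * 4
        for idx, ch, exc in g:
            t = idx / fs
            if per_ch[ch] is None or abs(exc["peak_z"]) > abs(per_ch[ch][1]):
                per_ch[ch] = (t, exc["peak_z"])
                spans[ch] = exc["span_ms"]
        n_ch = sum(p is not None for p in per_ch)
        if n_ch < 3:
            continue
        onset_t = min(p[0] for p in per_ch if p is not None)
        i0 = int(round(onset_t * fs)) - pre
        if i0 < 0 or i0 + pre + post > zrec.n_samples:
            continue
        events.append(IISEvent(
            onset=onset_t,
            per_channel_peaks=per_ch,
            n_channels=n_ch,
            waveform=zrec.samples[:, i0 : i0 + pre + post].copy(),
            spans_ms=spans,
        ))
    return events


def _centroid_is_spike(centroid: np.ndarray, fs: float, cfg: IISDetectionConfig) -> bool:
    """Re-apply the spike definition to a cluster centroid.

    A channel passes when the centroid crosses the threshold both above and
    below (biphasic) with crossing span <= 75 ms; the cluster is a spike
    class when >= 3 channels pass with coherent peak times.
    """
    peak_times = []
    for ch in range(centroid.shape[0]):
        c = centroid[ch]
        if c.max() < cfg.z_threshold or c.min() > -cfg.z_threshold:
            continue
        hot = np.nonzero(np.abs(c) >= cfg.z_threshold)[0]
        span_ms = (hot[-1] - hot[0] + 1) / fs * 1000.0
        if span_ms > cfg.max_duration_ms:
            continue
        peak_times.append(np.argmax(np.abs(c)) / fs)
    if len(peak_times) < 3:
        return False
    return (max(peak_times) - min(peak_times)) * 1000.0 <= cfg.coincidence_window_ms


def refine_templates(candidates: list[IISEvent], cfg: IISDetectionConfig,
                     seed: int | None = None) -> list[IISEvent]:
    """PCA + k-means template refinement and spike/artifact labeling.

    Snippets are projected on the first 10 principal components and
    clustered (k chosen in 5-10 by silhouette, seeded). Clusters whose
    centroid satisfies the spike definition become templates; events are
    then re-screened by normalized correlation against the templates
    (>= ``template_corr_min``) iteratively until the accepted set is
    stable. Returns the same events with ``cluster_id`` and ``label`` set.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    cfg.validate()
    seed = cfg.seed if seed is None else seed
    n = len(candidates)
    if n == 0:
        return candidates
    fs_ms = candidates[0].waveform.shape[1] / 200.0  # samples per ms (200-ms snippet)
    fs = fs_ms * 1000.0

    def threshold_label(ev: IISEvent) -> str:
        return "IIS" if ev.n_channels == 4 else "IIS-like"

    if n <= cfg.k_min:  # need k_min clusters plus one point for silhouette
        logger.info("only %d candidates (<= k_min=%d): keeping threshold-based labels",
                    n, cfg.k_min)
        for ev in candidates:
            ev.label = threshold_label(ev)
        return candidates

    X = np.stack([ev.waveform.ravel() for ev in candidates])
    n_pcs = min(cfg.n_pcs, n - 1, X.shape[1])
    pcs = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    best_k, best_score, best_labels = None, -np.inf, None
    for k in range(cfg.k_min, min(cfg.k_max, n - 1) + 1):
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(pcs)
        score = silhouette_score(pcs, km.labels_) if k > 1 else -np.inf
        if score > best_score:
            best_k, best_score, best_labels = k, score, km.labels_
    logger.info("k-means: k=%d (silhouette=%.3f) over %d candidates", best_k, best_score, n)

    for ev, cid in zip(candidates, best_labels):
        ev.cluster_id = int(cid)

    nsnip = candidates[0].waveform.shape
    spike_clusters = set()
    templates = []
    for cid in range(best_k):
        members = [ev for ev in candidates if ev.cluster_id == cid]
        centroid = np.mean([ev.waveform for ev in members], axis=0)
        if _centroid_is_spike(centroid, fs, cfg):
            spike_clusters.add(cid)
            templates.append(centroid.ravel())

    if not templates:
        for ev in candidates:
            ev.label = "artifact"
        return candidates

    accepted = np.zeros(n, dtype=bool)
    for it in range(cfg.max_template_iters):
        T = np.stack(templates)
        Tn = T / np.linalg.norm(T, axis=1, keepdims=True)
        Xn = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
        corr = Xn @ Tn.T
        new_accept = corr.max(axis=1) >= cfg.template_corr_min
        if np.array_equal(new_accept, accepted):
            logger.info("template iteration converged after %d pass(es)", it)
            break
        accepted = new_accept
        if accepted.sum() == 0:
            break
        # refine templates from the accepted events of each spike cluster
        templates = []
        for cid in spike_clusters:
            mem = [i for i in range(n) if candidates[i].cluster_id == cid and accepted[i]]
            if mem:
                templates.append(X[mem].mean(axis=0))
        if not templates:
            break

    for i, ev in enumerate(candidates):
        ev.label = threshold_label(ev) if accepted[i] else "artifact"
    return candidates


def spike_triggered_average(events: list[IISEvent], rec: Recording,
                            cfg: IISDetectionConfig | None = None) -> np.ndarray:
    """Mean 4 x 200-ms waveform (raw units) of labeled spikes, onset-aligned."""
    cfg = cfg or IISDetectionConfig()
    spikes = [ev for ev in events if ev.label in ("IIS", "IIS-like")]
    if not spikes:
        raise ValueError("no labeled spikes to average")
    fs = rec.sample_rate
    pre = int(round(cfg.waveform_pre_ms / 1000.0 * fs))
    post = int(round(cfg.waveform_post_ms / 1000.0 * fs))
    snips = []
    for ev in spikes:
        i0 = int(round(ev.onset * fs)) - pre
        if 0 <= i0 and i0 + pre + post <= rec.n_samples:
            snips.append(rec.samples[:, i0 : i0 + pre + post])
    if not snips:
        raise ValueError("no spike fits inside the recording for averaging")
    return np.mean(snips, axis=0)


def detect_iis(rec: Recording, baseline_epochs: Sequence[int],
               cfg: IISDetectionConfig | None = None) -> list[IISEvent]:
    """Full detection: z-score against baseline epochs, detect, refine."""
    cfg = cfg or IISDetectionConfig()
    zrec = channel_zscore(rec, baseline_epochs)
    cands = detect_candidates(zrec, cfg)
    return refine_templates(cands, cfg)
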