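"""State-conditional spike statistics, peri-event time histograms, and
injection-window comparisons.

Spike rates are conditioned on the behavioral state containing each event's
onset; ictal spans are excluded from both counts and durations, so rates
are interictal by construction. PETHs count event lags around behavioral
transitions (e.g. REM onset) over a +/-3 min window and are smoothed with a
3-s-SD Gaussian kernel; per-animal PETHs on the same grid average
unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import STATES
from .staging import Hypnogram

__all__ = [
    "iis_rate_by_state",
    "PETH",
    "build_peth",
    "average_peths",
    "InjectionComparison",
    "compare_injection_windows",
    "light_dark_occupancy",
]


def _interval_overlap(a: Sequence[tuple[float, float]],
                      s: float, e: float) -> float:
    """Total overlap of intervals ``a`` with [s, e)."""
    return sum(max(0.0, min(e, ae) - max(s, as_)) for as_, ae in a)


def _in_any(t: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return any(s <= t < e for s, e in intervals)


def iis_rate_by_state(event_times: Sequence[float], hypnogram: Hypnogram,
                      seizure_intervals: Sequence[tuple[float, float]] = ()
                      ) -> pd.DataFrame:
    """Interictal spike count, state time and rate per behavioral state.

    Events inside seizure intervals are dropped; ictal time is removed from
    the state durations. A state with zero (non-ictal) duration gets a NaN
    rate with ``defined = False`` — absence of exposure, not a zero rate.
    """
    times = sorted(float(t) for t in event_times)
    for t in times:
        if not (hypnogram.start <= t < hypnogram.end):
            raise ValueError(f"event at {t} s outside hypnogram span")
    seiz = [(float(s), float(e)) for s, e in seizure_intervals]
    counts = {s: 0 for s in STATES}
    durations = {s: 0.0 for s in STATES}
    for s0, e0, lab in hypnogram.intervals:
        durations[lab] += (e0 - s0) - _interval_overlap(seiz, s0, e0)
    for t in times:
        if _in_any(t, seiz):
            continue
        counts[hypnogram.label_at(t)] += 1
    rows = []
    for s in STATES:
        dur = durations[s]
        defined = dur > 0
        rows.append({
            "state": s, "count": counts[s], "duration_s": dur,
            "rate_per_hour": counts[s] / dur * 3600.0 if defined else np.nan,
            "rate_per_min": counts[s] / dur * 60.0 if defined else np.nan,
            "defined": defined,
        })
    df = pd.DataFrame(rows).set_index("state")
    # conservation: per-state time sums to hypnogram span minus ictal time
    total_ictal = _interval_overlap(seiz, hypnogram.start, hypnogram.end)
    assert abs(df["duration_s"].sum() - (hypnogram.duration - total_ictal)) < 1e-6
    return df


@dataclass
class PETH:
    """Peri-event time histogram of spike lags around a transition."""

    reference: str
    bin_edges: np.ndarray  # seconds, symmetric about 0
    raw_counts: np.ndarray
    smoothed_rate: np.ndarray  # events/min
    kernel_bandwidth_s: float
    n_references: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def gaussian_kernel_bins(bandwidth_s: float, bin_width_s: float) -> np.ndarray:
    """Discrete Gaussian (SD = bandwidth) on the bin grid, unit sum."""
    sigma = bandwidth_s / bin_width_s
    half = max(1, int(np.ceil(4.0 * sigma)))
    t = np.arange(-half, half + 1)
    k = np.exp(-(t ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def build_peth(event_times: Sequence[float], transition_times: Sequence[float],
               window_s: float = 180.0, bin_width_s: float = 1.0,
               bandwidth_s: float = 3.0, reference: str = "transition") -> PETH:
    """Histogram of event-minus-transition lags over +/-window, smoothed.

    The smoothed rate is events per minute per reference; smoothing uses a
    Gaussian kernel with SD ``bandwidth_s`` (the 3-s bandwidth convention)
    and preserves total mass away from the window edges.
    """
    if bin_width_s <= 0:
        raise ValueError("bin_width_s must be positive")
    refs = np.asarray(list(transition_times), dtype=float)
    if refs.size == 0:
        raise ValueError("no reference transitions")
    ev = np.asarray(list(event_times), dtype=float)
    lags = (ev[None, :] - refs[:, None]).ravel() if ev.size else np.empty(0)
    nbins = int(round(2 * window_s / bin_width_s))
    edges = np.linspace(-window_s, window_s, nbins + 1)
    counts, _ = np.histogram(lags, bins=edges)
    kernel = gaussian_kernel_bins(bandwidth_s, bin_width_s)
    smoothed = np.convolve(counts.astype(float), kernel, mode="same")
    rate = smoothed / (refs.size * bin_width_s) * 60.0
    return PETH(reference=reference, bin_edges=edges, raw_counts=counts,
                smoothed_rate=rate, kernel_bandwidth_s=bandwidth_s,
                n_references=refs.size)


def average_peths(peths: Sequence[PETH]) -> PETH:
    """Unweighted mean of per-animal PETHs on identical grids."""
    if not peths:
        raise ValueError("nothing to average")
    first = peths[0]
    for p in peths[1:]:
        if p.bin_edges.shape != first.bin_edges.shape or \
                not np.allclose(p.bin_edges, first.bin_edges):
            raise ValueError("PETH grids differ; cannot average")
    return PETH(
        reference=first.reference,
        bin_edges=first.bin_edges,
        raw_counts=np.mean([p.raw_counts for p in peths], axis=0),
        smoothed_rate=np.mean([p.smoothed_rate for p in peths], axis=0),
        kernel_bandwidth_s=first.kernel_bandwidth_s,
        n_references=sum(p.n_references for p in peths),
    )


def _nrem_restricted_rate(event_times: Sequence[float], hypnogram: Hypnogram,
                          window: tuple[float, float]) -> tuple[float, int, float, bool]:
    s0, e0 = window
    nrem_s = 0.0
    for s, e, lab in hypnogram.intervals:
        if lab == "NREM":
            nrem_s += max(0.0, min(e, e0) - max(s, s0))
    count = sum(
        1 for t in event_times
        if s0 <= t < e0 and hypnogram.start <= t < hypnogram.end
        and hypnogram.label_at(t) == "NREM"
    )
    defined = nrem_s > 0
    rate = count / nrem_s * 3600.0 if defined else np.nan
    return rate, count, nrem_s, defined


@dataclass
class InjectionComparison:
    """NREM-restricted spike rates before/after a drug injection."""

    baseline_rate_per_hour: float
    post_rate_per_hour: float
    baseline_defined: bool
    post_defined: bool
    rate_ratio: float  # post / baseline (NaN when either side undefined)
    baseline_count: int
    post_count: int
    time_in_state: pd.DataFrame  # fraction of each window per state


def compare_injection_windows(event_times: Sequence[float], hypnogram: Hypnogram,
                              injection_time: float, horizon_s: float = 4 * 3600.0,
                              baseline_window: tuple[float, float] | None = None
                              ) -> InjectionComparison:
    """Post-injection (0-4 h) vs baseline NREM-restricted spike rates.

    ``baseline_window`` defaults to everything before the injection. Windows
    with no NREM sleep are flagged undefined rather than reported as zero —
    the analysis excludes sleepless windows instead of diluting them.
    """
    if not (hypnogram.start <= injection_time < hypnogram.end):
        raise ValueError("injection_time outside the recording")
    base = baseline_window or (hypnogram.start, injection_time)
    post = (injection_time, min(injection_time + horizon_s, hypnogram.end))
    b_rate, b_count, _, b_def = _nrem_restricted_rate(event_times, hypnogram, base)
    p_rate, p_count, _, p_def = _nrem_restricted_rate(event_times, hypnogram, post)
    ratio = p_rate / b_rate if (b_def and p_def and b_rate > 0) else np.nan

    rows = []
    for name, (w0, w1) in (("baseline", base), ("post", post)):
        span = w1 - w0
        for state in STATES:
            dur = sum(max(0.0, min(e, w1) - max(s, w0))
                      for s, e, lab in hypnogram.intervals if lab == state)
            rows.append({"window": name, "state": state, "seconds": dur,
                         "fraction": dur / span if span > 0 else np.nan})
    return InjectionComparison(
        baseline_rate_per_hour=b_rate, post_rate_per_hour=p_rate,
        baseline_defined=b_def, post_defined=p_def, rate_ratio=ratio,
        baseline_count=b_count, post_count=p_count,
        time_in_state=pd.DataFrame(rows),
    )


def light_dark_occupancy(hypnogram: Hypnogram, light_onset_s: float,
                         period_s: float = 12 * 3600.0) -> pd.DataFrame:
    """Per-state time in the light vs dark photoperiod.

    Photoperiods alternate with ``period_s`` starting light at
    ``light_onset_s``; time before the first light onset counts as dark.
    Durations sum to the hypnogram span by construction.
    """
    if period_s <= 0:
        raise ValueError("period_s must be positive")
    if light_onset_s >= hypnogram.end:
        raise ValueError("light_onset_s beyond the recording")
    # build alternating (start, end, phase) blocks covering the span
    blocks: list[tuple[float, float, str]] = []
    t = light_onset_s
    while t > hypnogram.start:
        t -= period_s
    # t is light_onset - k*period; phase alternates, light starting at onset
    k = int(round((light_onset_s - t) / period_s))
    phase = "light" if k % 2 == 0 else "dark"
    while t < hypnogram.end:
        blocks.append((t, t + period_s, phase))
        phase = "dark" if phase == "light" else "light"
        t += period_s
    out = {s: {"light": 0.0, "dark": 0.0} for s in STATES}
    for s0, e0, lab in hypnogram.intervals:
        for b0, b1, ph in blocks:
            out[lab][ph] += max(0.0, min(e0, b1) - max(s0, b0))
    df = pd.DataFrame(
        [{"state": s, "light_s": out[s]["light"], "dark_s": out[s]["dark"]}
         for s in STATES]
    ).set_index("state")
    assert abs(df.to_numpy().sum() - hypnogram.duration) < 1e-6
    return df
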