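"""Independent reference implementations used by several test modules."""

from __future__ import annotations

import numpy as np

from somnispike.staging import Hypnogram


def oracle_episodes(intervals, step=0.5, min_dur=300.0, brief=3.0):
    """Linear-scan sleep-episode enumeration on a fine label sequence."""
    end = intervals[-1][1]
    n = int(round(end / step))
    labels = []
    j = 0
    for i in range(n):
        t = (i + 0.5) * step
        while t >= intervals[j][1] and j < len(intervals) - 1:
            j += 1
        labels.append(intervals[j][2])
    sleep = {"NREM", "REM"}
    episodes = []
    i = 0
    while i < n:
        if labels[i] != "NREM":
            i += 1
            continue
        start = i
        count_trans = 0
        count_brief = 0
        last_sleep = "NREM"
        last_sleep_end = i + 1
        k = i + 1
        while k < n:
            if labels[k] in sleep:
                if labels[k] != last_sleep:
                    count_trans += 1
                last_sleep = labels[k]
                last_sleep_end = k + 1
                k += 1
            else:
                m = k
                while m < n and labels[m] not in sleep:
                    m += 1
                wake = (m - k) * step
                if wake < brief and m < n:
                    count_brief += 1
                    k = m
                else:
                    break
        dur = (last_sleep_end - start) * step
        if dur > min_dur:
            episodes.append((start * step, last_sleep_end * step,
                             count_trans, count_brief))
        i = k
    return episodes


def oracle_sfi_count(intervals) -> int:
    """Total fragmentation count: transitions plus brief arousals."""
    return sum(e[2] + e[3] for e in oracle_episodes(intervals))


def random_sleepy_hypnogram(rng) -> Hypnogram:
    states = ["NREM", "REM", "QW", "AW"]
    probs = [0.5, 0.2, 0.2, 0.1]
    t, ivs = 0.0, []
    for _ in range(rng.integers(5, 40)):
        lab = states[rng.choice(4, p=probs)]
        if lab in ("QW", "AW"):
            dur = float(rng.choice([0.5, 1, 2, 2.5, 4, 10, 30]))
        else:
            dur = float(rng.choice([10, 30, 60, 120, 240]))
        ivs.append((t, t + dur, lab))
        t += dur
    return Hypnogram(intervals=ivs)


def random_hypnogram(rng) -> Hypnogram:
    states = ["AW", "QW", "NREM", "REM"]
    t, ivs = 0.0, []
    for _ in range(rng.integers(3, 25)):
        dur = float(rng.choice([0.5, 1, 2, 3, 5, 10, 30]))
        ivs.append((t, t + dur, states[rng.integers(4)]))
        t += dur
    return Hypnogram(intervals=ivs)
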