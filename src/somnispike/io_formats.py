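"""On-disk formats: EDF signals, CSV events/hypnograms/velocity, YAML config.

Conventions used throughout the package:

* all event and interval times are seconds from recording start,
* intervals are half-open ``[start, end)``,
* the scoring grid is anchored at t = 0 with fixed 10-s epochs and the last
  partial epoch discarded,
* event times round-trip through CSV at millisecond precision.

EDF reading goes through :mod:`mne`; writing uses a minimal 16-bit EDF
encoder implemented here (one 1-s data record per second, physical units
microvolts).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import CHANNEL_ROLES, STATES

__all__ = [
    "Recording",
    "VelocityTrace",
    "read_edf",
    "write_edf",
    "write_events",
    "read_events",
    "write_hypnogram",
    "read_hypnogram",
    "write_velocity",
    "read_velocity",
]

#: substrings (upper-cased) that map an EDF channel label to a role
DEFAULT_CHANNEL_ALIASES: dict[str, tuple[str, ...]] = {
    "FC": ("FC", "FRONTAL"),
    "OC": ("OC", "OCCIP"),
    "LHC": ("LHC", "LEFT HIPP", "L HIPP"),
    "RHC": ("RHC", "RIGHT HIPP", "R HIPP"),
}


@dataclass
class Recording:
    """4-channel EEG in canonical role order (FC, OC, LHC, RHC), microvolts."""

    samples: np.ndarray  # (4, n) float
    sample_rate: float
    channel_roles: tuple[str, ...] = CHANNEL_ROLES
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_roles):
            raise ValueError(
                f"samples must be ({len(self.channel_roles)}, n), got {self.samples.shape}"
            )
        if tuple(self.channel_roles) != CHANNEL_ROLES:
            raise ValueError(f"channel_roles must be {CHANNEL_ROLES} in order")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if np.isnan(self.samples).any():
            raise ValueError("recording contains NaN samples")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, role: str) -> np.ndarray:
        return self.samples[self.channel_roles.index(role)]


@dataclass
class VelocityTrace:
    """Animal speed from positional tracking, cm/s, typically 10 Hz."""

    values: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("velocity values must be 1-D")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if np.any(self.values < 0):
            raise ValueError("velocity must be non-negative")

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate


# ---------------------------------------------------------------------------
# EDF


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {text!r} > {width} bytes")
    return b.ljust(width)


def write_edf(rec: Recording, path, signal_order: Sequence[int] | None = None) -> None:
    """Write a Recording as 16-bit EDF, one 1-s data record per second.

    The physical range is chosen per channel from the data extremes, so the
    worst-case round-trip error is one quantization step. Header dates are
    fixed (not wall-clock) so identical recordings produce identical files.
    ``signal_order`` optionally permutes the order signals appear in the
    file (labels follow the data, so role mapping is unaffected).
    """
    order = list(signal_order) if signal_order is not None else list(range(4))
    if sorted(order) != [0, 1, 2, 3]:
        raise ValueError("signal_order must be a permutation of 0..3")
    fs = rec.sample_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sample rate")
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one 1-s EDF data record")
    data = rec.samples[order, : n_records * spr]
    roles = [rec.channel_roles[i] for i in order]

    nch = data.shape[0]
    header_bytes = 256 * (1 + nch)
    dig_min, dig_max = -32768, 32767
    phys_min = np.empty(nch)
    phys_max = np.empty(nch)
    for i in range(nch):
        amp = max(np.max(np.abs(data[i])), 1e-6)
        phys_max[i] = amp
        phys_min[i] = -amp

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(nch), 4))
        for role in roles:
            fh.write(_pad(f"EEG {role}", 16))
        for _ in range(nch):
            fh.write(_pad("", 80))
        for _ in range(nch):
            fh.write(_pad("uV", 8))
        for v in phys_min:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in phys_max:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for _ in range(nch):
            fh.write(_pad(str(dig_min), 8))
        for _ in range(nch):
            fh.write(_pad(str(dig_max), 8))
        for _ in range(nch):
            fh.write(_pad("BP 0.5-200 Hz", 80))
        for _ in range(nch):
            fh.write(_pad(str(spr), 8))
        for _ in range(nch):
            fh.write(_pad("", 32))

        # phys min/max written with limited ASCII precision: recompute the
        # scale from the values actually stored so read-back is consistent
        pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
        pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
        scale = (pmax - pmin) / (dig_max - dig_min)
        for r in range(n_records):
            block = data[:, r * spr : (r + 1) * spr]
            for i in range(nch):
                dig = np.round((block[i] - pmin[i]) / scale[i]) + dig_min
                dig = np.clip(dig, dig_min, dig_max).astype("<i2")
                fh.write(dig.tobytes())


def _edf_samples_per_record(path) -> list[int]:
    """Peek at the EDF signal headers for per-signal samples-per-record."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        nch = int(head[252:256].decode("ascii").strip())
        sig = fh.read(256 * nch)
    off = nch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    out = []
    for i in range(nch):
        fld = sig[off + 8 * i : off + 8 * (i + 1)]
        out.append(int(fld.decode("ascii").strip()))
    return out


def _match_role(label: str, aliases: dict[str, tuple[str, ...]]) -> str | None:
    up = label.upper()
    for role, pats in aliases.items():
        if any(p in up for p in pats):
            return role
    return None


def read_edf(path, aliases: dict[str, tuple[str, ...]] | None = None) -> Recording:
    """Read an EDF/EDF+ file into a canonical-order Recording (microvolts).

    Channel labels are mapped to roles through a substring alias table; all
    four roles must be present and share one sampling rate.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    aliases = aliases or DEFAULT_CHANNEL_ALIASES

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    role_to_idx: dict[str, int] = {}
    for i, name in enumerate(raw.ch_names):
        role = _match_role(name, aliases)
        if role is not None and role not in role_to_idx:
            role_to_idx[role] = i
    missing = [r for r in CHANNEL_ROLES if r not in role_to_idx]
    if missing:
        raise ValueError(f"EDF {path.name}: no channel maps to role(s) {missing}")

    spr = _edf_samples_per_record(path)
    rates = {spr[role_to_idx[r]] for r in CHANNEL_ROLES}
    if len(rates) > 1:
        raise ValueError(f"EDF {path.name}: mixed sampling rates across EEG signals: {sorted(rates)}")

    data = raw.get_data()[[role_to_idx[r] for r in CHANNEL_ROLES]] * 1e6  # V -> uV
    if np.isnan(data).any():
        raise ValueError(f"EDF {path.name}: NaN samples after load")
    return Recording(samples=data, sample_rate=float(raw.info["sfreq"]))


# ---------------------------------------------------------------------------
# CSV dialects

_EVENT_BASE_COLS = ["time_s", "ch_FC", "ch_OC", "ch_LHC", "ch_RHC"]


def write_events(events: pd.DataFrame | Iterable, path) -> None:
    """Write an event table; times stored at millisecond precision.

    Accepts a DataFrame with at least ``time_s`` and per-channel mask
    columns, or any iterable of objects with ``onset`` and ``channel_mask``
    attributes (e.g. detected spike events).
    """
    if isinstance(events, pd.DataFrame):
        df = events.copy()
    else:
        rows = []
        for ev in events:
            row = {"time_s": ev.onset}
            mask = getattr(ev, "channel_mask", (True,) * 4)
            for role, m in zip(CHANNEL_ROLES, mask):
                row[f"ch_{role}"] = bool(m)
            for extra in ("n_channels", "label", "cluster_id", "peak_z"):
                if hasattr(ev, extra):
                    row[extra] = getattr(ev, extra)
            rows.append(row)
        df = pd.DataFrame(rows, columns=None)
        if df.empty:
            df = pd.DataFrame(columns=_EVENT_BASE_COLS)
    df["time_s"] = np.round(df["time_s"].astype(float), 3)
    for role in CHANNEL_ROLES:
        col = f"ch_{role}"
        if col in df:
            df[col] = df[col].astype(bool).astype(int)
    df.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: event file lacks a time_s column")
    for role in CHANNEL_ROLES:
        col = f"ch_{role}"
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def write_hypnogram(labels: Sequence[str], path, epoch_length_s: float = 10.0) -> None:
    df = pd.DataFrame(
        {"epoch_index": np.arange(len(labels), dtype=int), "label": list(labels)}
    )
    with open(path, "w") as fh:
        fh.write(f"# epoch_length_s={epoch_length_s:g}\n")
        df.to_csv(fh, index=False)


def read_hypnogram(path) -> tuple[list[str], float]:
    """Read an epoch-label hypnogram CSV; returns (labels, epoch_length_s)."""
    epoch_length = 10.0
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "epoch_length_s=" in first:
                epoch_length = float(first.split("epoch_length_s=")[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    labels = [str(x) for x in df["label"]]
    for i, lab in enumerate(labels):
        if lab not in STATES:
            raise ValueError(
                f"{path}: unknown state label {lab!r} at row {i} (epoch_index="
                f"{df['epoch_index'].iloc[i]})"
            )
    return labels, epoch_length


def write_velocity(v: VelocityTrace, path) -> None:
    pd.DataFrame(
        {"time_s": np.round(v.times, 6), "velocity_cms": v.values}
    ).to_csv(path, index=False)


def read_velocity(path) -> VelocityTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(float)
    if len(t) < 2:
        raise ValueError(f"{path}: velocity trace needs at least 2 samples")
    dt = np.median(np.diff(t))
    return VelocityTrace(values=df["velocity_cms"].to_numpy(float), sample_rate=1.0 / dt)
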