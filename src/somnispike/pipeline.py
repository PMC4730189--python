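"""End-to-end orchestration: simulate (or load) -> stage -> detect -> analyze.

One config plus one seed fully determines every output; a JSON run manifest
records the config hash, effective thresholds, stage timings and warnings,
so a run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig, config_to_yaml
from .events import build_peth, iis_rate_by_state
from .iis import detect_iis
from .io_formats import (Recording, read_edf, read_velocity, write_edf,
                         write_events, write_hypnogram, write_velocity)
from .seizures import detect_seizures
from .spectral import epoch_psd, preprocess
from .staging import (classify_epochs, find_sleep_episodes,
                      sleep_fragmentation_index)
from .synthetic import generate_recording

__all__ = ["RunManifest", "run_all"]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, sort_keys=True)


def _stage(name: str, manifest: RunManifest):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest.timings_s[name] = round(time.perf_counter() - self.t0, 3)
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    return _Ctx()


def run_all(config: PipelineConfig, seed: int, out_dir,
            write_signals: bool = False) -> RunManifest:
    """Run the full pipeline into ``out_dir``; deterministic given the seed.

    The seed overrides the generator and detector seeds in the config. Each
    stage writes its outputs before the next starts, so a failure leaves
    prior results intact. ``write_signals`` additionally exports the EDF and
    velocity CSV (large for long sessions).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.generator.seed = seed
    config.iis.seed = seed
    cfg_yaml = config_to_yaml(config)
    manifest = RunManifest(
        config_hash=hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        seed=seed, version=__version__,
    )
    (out / "config.yaml").write_text(cfg_yaml)
    manifest.outputs["config"] = str(out / "config.yaml")

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        with _stage("acquire", manifest):
            if config.input_edf:
                p = Path(config.input_edf)
                if not p.exists():
                    raise FileNotFoundError(f"input EDF not found: {p}")
                rec = read_edf(p)
                vel = read_velocity(config.input_velocity) if config.input_velocity else None
                truth = None
            else:
                rec, vel, truth = generate_recording(config.generator)
                truth.to_json(out / "ground_truth.json")
                manifest.outputs["ground_truth"] = str(out / "ground_truth.json")
            if write_signals:
                write_edf(rec, out / "recording.edf")
                manifest.outputs["edf"] = str(out / "recording.edf")
                if vel is not None:
                    write_velocity(vel, out / "velocity.csv")
                    manifest.outputs["velocity"] = str(out / "velocity.csv")
            if vel is None:
                raise ValueError("staging requires a velocity trace")

        with _stage("spectra", manifest):
            ds = preprocess(rec, config.analysis)
            spectra = epoch_psd(ds, config.analysis, channel_role="FC")

        with _stage("stage", manifest):
            hyp = classify_epochs(spectra, vel, config.staging)
            write_hypnogram(hyp.to_labels(), out / "hypnogram.csv",
                            epoch_length_s=hyp.epoch_length_s)
            manifest.outputs["hypnogram"] = str(out / "hypnogram.csv")

        with _stage("detect_iis", manifest):
            labels = hyp.to_labels()
            baseline = [i for i, lab in enumerate(labels)
                        if lab in ("NREM", "QW") and not spectra.artifact[i]]
            events = detect_iis(rec, baseline, config.iis)
            write_events(events, out / "events.csv")
            manifest.outputs["events"] = str(out / "events.csv")

        with _stage("detect_seizures", manifest):
            seiz = detect_seizures(ds, hyp, config.seizure, config.analysis)
            pd.DataFrame(
                [{"start_s": s.start, "end_s": s.end,
                  "trigger_channel": s.trigger_channel, "peak_z": s.peak_z}
                 for s in seiz],
                columns=["start_s", "end_s", "trigger_channel", "peak_z"],
            ).to_csv(out / "seizures.csv", index=False)
            manifest.outputs["seizures"] = str(out / "seizures.csv")

        with _stage("analyze", manifest):
            spikes = [ev.onset for ev in events if ev.label == "IIS"]
            ictal = [(s.start, s.end) for s in seiz]
            rates = iis_rate_by_state(spikes, hyp, ictal)
            rates.to_csv(out / "iis_rates.csv")
            manifest.outputs["iis_rates"] = str(out / "iis_rates.csv")

            rem_onsets = hyp.transitions(from_state="NREM", to_state="REM")
            if rem_onsets and spikes:
                peth = build_peth(spikes, rem_onsets, reference="REM onset")
                pd.DataFrame({
                    "lag_s": peth.bin_centers,
                    "raw_count": peth.raw_counts,
                    "rate_per_min": peth.smoothed_rate,
                }).to_csv(out / "peth_rem_onset.csv", index=False)
                manifest.outputs["peth"] = str(out / "peth_rem_onset.csv")

            episodes = find_sleep_episodes(hyp)
            sfi = sleep_fragmentation_index(episodes, hyp)
            sfi.per_episode.to_csv(out / "sleep_episodes.csv", index=False)
            manifest.outputs["sleep_episodes"] = str(out / "sleep_episodes.csv")

            summary = {
                "n_iis": len(spikes),
                "n_iis_like": sum(1 for ev in events if ev.label == "IIS-like"),
                "n_artifact_events": sum(1 for ev in events if ev.label == "artifact"),
                "n_seizures": len(seiz),
                "sfi_per_hour": sfi.sfi,
                "sfi_total_count": sfi.total_count,
                "state_seconds": hyp.state_durations(),
                "iis_rate_per_hour": {
                    s: (None if not rates.loc[s, "defined"]
                        else rates.loc[s, "rate_per_hour"])
                    for s in rates.index
                },
            }
            with open(out / "summary.json", "w") as fh:
                json.dump(summary, fh, indent=1, sort_keys=True)
            manifest.outputs["summary"] = str(out / "summary.json")

    manifest.warnings = [str(w.message) for w in caught]
    manifest.to_json(out / "manifest.json")
    return manifest
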