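# somnispike

Sleep staging, interictal-spike detection and seizure detection for
chronic rodent video-EEG, with state-conditional event statistics and a
ground-truth synthetic EEG generator.

## The problem

In mouse models of amyloid pathology (and in epilepsy models generally),
interictal spikes (IIS) — brief, large, synchronized EEG transients —
appear long before overt seizures and cluster in specific behavioral
states, especially REM sleep. Quantifying that requires a chain of
analyses on 24-h multichannel EEG: scoring behavioral state on a 10-s
grid, detecting spikes with amplitude/duration/synchrony rules, rejecting
cable artifacts, flagging ictal segments, and then computing spike rates
conditional on state, peri-event histograms around state transitions, and
sleep-fragmentation scores. `somnispike` implements that chain as a
tested, reusable library and CLI for 4-channel recordings (frontal
cortex, occipital cortex, left/right hippocampus).

## The rules at the core

* **Staging** (per 10-s epoch, frontal channel): movement > 3 s → active
  wake; else θ/δ band-power ratio > 2.5 (θ: 5–10 Hz, δ: 0.5–4 Hz) with
  prior state NREM → REM; else wideband (0.5–200 Hz) power > 1 z above
  quiet wakefulness sustained ≥ 3 s → NREM; else quiet wakefulness. REM
  runs separated by < 3 s are merged.
* **IIS**: |z| ≥ 7 above *and* below the per-channel baseline, crossing
  span ≤ 75 ms, coincident on ≥ 3 of 4 channels; refined by PCA +
  k-means template clustering that rejects artifact waveform families.
* **Seizures**: wideband log-power in 2-s Hann windows ≥ 4 z for ≥ 5 s on
  any channel.
* **SFI**: NREM/REM transitions plus brief (< 3 s) arousals within sleep
  episodes (> 5 min, NREM-initiated), per hour of episode sleep.
* **Spectra**: 10-s Hann-taper FFT power, z-scored per frequency bin
  against quiet wakefulness; 7-cycle Morlet wavelets for time-frequency.

Because no recordings ship with the package, a synthetic generator
produces 4-channel EEG with Markov-chain behavioral states,
state-conditioned spectra (REM theta, NREM delta), state-conditional
Poisson spikes, cable artifacts, movement bouts and optional seizures —
plus the ground truth, so every stage is verifiable end to end. See
`docs/methods.md` for the full model and its limitations.

## Worked example

Simulate one hour and run the whole pipeline:

```bash
somnispike run --out run/ --seed 7
```

or from Python:

```python
from somnispike import PipelineConfig, GeneratorConfig
from somnispike.pipeline import run_all

cfg = PipelineConfig()
cfg.generator = GeneratorConfig(duration_s=3600.0)
run_all(cfg, seed=7, out_dir="run")
print(open("run/summary.json").read())
```

which prints (numbers from this exact seed):

```json
{
 "iis_rate_per_hour": {
  "AW": 0.0,
  "NREM": 6.352941176470589,
  "QW": 0.0,
  "REM": 12.0
 },
 "n_artifact_events": 0,
 "n_iis": 4,
 "n_iis_like": 0,
 "n_seizures": 0,
 "sfi_per_hour": 30.229007633587788,
 "sfi_total_count": 11,
 "state_seconds": {
  "AW": 970.0,
  "NREM": 1700.0,
  "QW": 630.0,
  "REM": 300.0
 }
}
```

Reading this: the detector found 4 interictal spikes in the hour, none
rejected as artifacts; the spike rate in REM sleep (12/h) exceeds NREM
(6.4/h) and wake is spike-free — the state-dependence the analysis is
built to expose. The generator's true rates are 30/h in REM and 5/h in
NREM; with only 5 minutes of REM in this hour the Poisson error on the
REM rate is wide, which is exactly why the full analyses run on much
longer sessions. The SFI says sleep was interrupted ~30 times per hour
of episode sleep (11 fragmentation events). `run/` also
contains the staged hypnogram, the labeled event table, seizure table,
per-state rate table, the REM-onset PETH and a JSON run manifest with the
config hash and per-stage timings. Other subcommands (`simulate`,
`spectra`, `stage`, `detect-iis`, `detect-seizures`, `analyze`) expose
the stages individually over EDF/CSV files.

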