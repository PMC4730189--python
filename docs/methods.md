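# Methods

This note documents the models, rules and numerical choices behind
`somnispike`: a pipeline for staging rodent behavioral state from chronic
4-channel EEG, detecting interictal spikes (IIS) and seizures, and
summarizing spike statistics conditional on behavioral state. It also
documents the synthetic-data generator that the test suite uses as ground
truth, and what passing those tests does and does not establish about real
recordings.

## Recording model

A recording is a 4-channel EEG in a fixed role order — frontal cortex
(FC), occipital cortex (OC), left and right dorsal hippocampus (LHC, RHC)
— in microvolts, nominally acquired at 2000 Hz and bandpass filtered
0.5–200 Hz. All event and interval times are seconds from recording
start; intervals are half-open `[start, end)`. The scoring grid is
anchored at t = 0 with fixed 10-s epochs; a trailing partial epoch is
discarded. A co-registered velocity trace (cm/s, nominally 10 Hz, from
video tracking) accompanies the EEG.

## Spectral quantification

Signals are anti-alias filtered and downsampled to 1000 Hz
(`scipy.signal.resample_poly`), cut into 10-s epochs, and transformed with
a single Hann-taper FFT. Power is a one-sided density (µV²/Hz), so the
integral over frequency matches the epoch variance (Parseval, verified to
1% in tests) and band summaries are insensitive to epoch length. Band
powers integrate the density over theta (5–10 Hz), delta (0.5–4 Hz),
sigma (10–15 Hz, a spindle-band proxy) and wideband (0.5–200 Hz) by the
trapezoid rule.

Power is standardized per frequency bin as a z-score against the mean and
SD over quiet-wakefulness (QW) epochs of the same session; the QW epochs
therefore have per-bin mean 0 and SD 1 by construction. The same reference
standardizes 1-s subwindow wideband log-power (used by the sustained-power
staging criterion) and band powers. Fewer than two artifact-free reference
epochs, or a zero-variance bin, is an error rather than a silent fallback.

Epochs containing sample excursions beyond 10 robust z (median/MAD scale)
on any channel — outside ±100 ms of known spike times — or overlapping
declared artifact times are flagged as contaminated. Flagged epochs stay
on the grid (the hypnogram must tile the recording) but are excluded from
reference statistics and from spectral summaries such as the peak-theta
distribution.

Peak theta frequency per REM epoch is the largest *interior* local maximum
of the power spectrum within 5–10 Hz; an epoch with no interior maximum
falls back to the band-restricted argmax.

Time-frequency maps use a complex Morlet wavelet with a constant 7-cycle
density: at frequency f the Gaussian envelope has SD `7 / (2πf)`,
truncated at ±4 SD and L2-normalized, applied by FFT convolution. The
wavelet is implemented directly because a constant cycle count across
frequencies cannot be expressed with a single fixed-bandwidth mother
wavelet. The default grid spans 1–55 Hz at quarter-octave spacing
(configurable). Wavelet power is z-scored per frequency against
quiet-wake samples, mirroring the FFT standardization.

## Behavioral-state staging

Each 10-s epoch is labeled active wakefulness (AW), quiet wakefulness
(QW), NREM or REM by a fixed rule order, using the FC channel:

1. **Movement** above a velocity floor (default 0.5 cm/s on the smoothed
   trace) for more than 3 s within the epoch → AW. The velocity trace is
   smoothed with a Gaussian kernel (SD 500 ms, reflect padding).
   "More than 3 s" is total supra-floor time within the epoch; the
   generator produces sustained bouts, for which total and consecutive
   time coincide.
2. **Theta/delta ratio** of raw band powers > 2.5 *and* the running prior
   label NREM (or an ongoing REM run) → REM. The prior-state criterion
   encodes the normal rodent sleep pattern: REM is entered from NREM. The
   ratio uses raw (not z-scored) band powers, making it invariant to
   global signal scaling. The first epoch of a recording cannot be REM.
3. **Sustained wideband power**: at least 3 consecutive 1-s subwindows
   with wideband log-power more than 1 z above the quiet-wake reference →
   NREM. The 1-s subwindow construction reconciles the 10-s scoring epoch
   with the 3-s persistence requirement. An optional delta-power z
   criterion exists but is off by default.
4. Otherwise → QW.

REM runs separated by less than 3 s are merged (the intervening span is
absorbed); merging is idempotent. After merging, every REM interval is
immediately preceded by NREM — an invariant the test suite asserts on
randomized inputs.

**Reference bootstrap.** Standardization needs QW epochs, but QW is itself
a staging output. Among non-movement, artifact-free epochs, quiet wake is
the mode that is low in *both* delta power (the defining slow-wave
feature of NREM, and the strongest QW/NREM separator) and wideband power.
The reference is the low cluster of a seeded two-means split on the
standardized log of those two band powers, minus theta-dominant
(REM-like) epochs via the theta/delta ≤ 2.5 filter. The reference is
deliberately *not* re-estimated from the classified labels afterwards:
experiments showed a contamination feedback in which misclassified NREM
epochs entering the reference inflate its spread and pull true NREM below
the sustained 1-z criterion, degrading accuracy. One conservative pass is
both simpler and more accurate; on synthetic sessions the bootstrapped
reference is > 98% pure quiet wake.

**Sleep episodes and fragmentation.** A sleep episode begins with NREM,
tolerates arousals (wake interruptions) shorter than 3 s, ends when an
arousal lasts 3 s or longer (that terminal arousal is not counted inside
the episode), and counts only if longer than 5 minutes. Within an
episode, the fragmentation count is the number of NREM↔REM transitions
(a switch counts once, including across a brief arousal) plus the number
of brief arousals. The sleep fragmentation index (SFI) is the total count
divided by hours of sleep inside episodes; raw counts are reported
alongside, since the normalization is a package choice made so recordings
with unequal sleep amounts are comparable.

**Automated staging.** A random forest (scikit-learn, 200 trees, seeded)
can be trained on per-epoch features: log band powers (theta, delta,
sigma, wideband), theta/delta ratio, velocity mean/max, and per-channel
log variance. Sigma power stands in for spindle presence as a soft
feature rather than a hard rule. All four states must be present in
training labels. At prediction time the REM-entry rule is enforced
sequentially: a predicted REM epoch whose running prior is wake is
reassigned to its most probable non-REM class.

## Interictal spike detection

An IIS is a transient, biphasic, large-amplitude event synchronized
across recording channels: threshold-crossing span ≤ 75 ms and amplitude
reaching 7 z both above and below the per-channel baseline mean. Events
on all 4 channels are labeled `IIS`; events on exactly 3 are `IIS-like`.

1. **Baseline z-scoring.** Each channel is z-scored against artifact-free
   NREM + QW epochs using median and MAD×1.4826 — robust to the spikes
   themselves sitting inside the baseline span. A constant channel (zero
   MAD) is an error.
2. **Candidates.** Per channel, runs of |z| ≥ 7 separated by less than
   75 ms form one excursion (the two phases of a biphasic transient);
   excursions whose first-to-last crossing span exceeds 75 ms are
   rejected — the transience rule. Channel peaks within a ±50 ms
   coincidence window group into one event; groups on ≥ 3 channels
   survive. Groups closer than 200 ms merge (refractory), so multiphasic
   spikes count once. Onset is the earliest channel peak; a 4 × 200 ms
   snippet (−50/+150 ms) is extracted per event.
3. **Template refinement.** Snippets are projected onto the first 10
   principal components and k-means clustered, k chosen in 5–10 by
   silhouette with a fixed seed (with ≤ k+1 candidates, threshold labels
   stand and the skip is logged). A cluster is a spike class when its
   centroid re-satisfies the definition: ≥ 3 channels crossing the
   threshold in both polarities with span ≤ 75 ms and coherent peak
   times. Latency-jittered or monophasic artifact families fail this at
   the centroid level even when individual members passed the per-event
   screen. Spike-cluster centroids become templates; events are
   re-screened by normalized correlation (≥ 0.7) against the templates,
   templates re-averaged from accepted events, iterating (≤ 5 passes)
   until the accepted set is stable. Rejected events are labeled
   `artifact`.

The spike-triggered average is the per-channel mean of raw snippets
aligned on onset.

## Seizure detection

Wideband (0.5–200 Hz) power is computed in 2-s non-overlapping Hann
windows per channel and log-transformed (variance stabilization). The z
location is the quiet-wake window mean — the same session convention as
the spectral standardization — but the z *scale* is the session-wide
robust SD (MAD×1.4826) of window power. The scale choice matters: on a
stationary quiet-wake reference the spread is so small that the ordinary
1.5–2× power elevation of NREM sleep (which the staging rule itself
requires) would exceed 4 z, flagging normal sleep as ictal. Against the
session-wide scale, state-dependent differences stay near 1 z while
ictal surges (≥ 10× power) land at 15 z and above. Runs of at least 3
consecutive windows with z ≥ 4 — the realization of "at least 5 s" on a
2-s grid — on any single channel become events; overlapping per-channel
runs merge into one event with the earliest start, latest end, and the
trigger channel of the largest peak z.

## Event analysis

State-conditional spike rates assign each event to the behavioral-state
interval containing its onset; ictal spans are removed from both counts
and durations, so rates are interictal by construction. Rates are
reported per hour and per minute; a state with zero non-ictal time is
flagged undefined rather than zero (no exposure is not a zero rate). The
per-state durations always sum to the hypnogram span minus ictal time.

Peri-event time histograms count event-minus-reference lags in 1-s bins
over ±180 s around behavioral transitions (e.g. NREM→REM onset) and are
smoothed with a discrete Gaussian kernel of SD 3 s ("bandwidth"
interpreted as the kernel SD), normalized to unit sum so mass is
preserved away from the window edges. Rates are events/min per
reference. Per-animal PETHs on identical grids average unweighted.

Injection-window comparisons compute NREM-restricted spike rates in the
4 h after an injection versus a baseline window (default: everything
before the injection), plus per-state time fractions in both windows. A
window without NREM sleep is flagged undefined, mirroring the exclusion
of sleepless post-injection animals rather than diluting their rates.
Light/dark occupancy partitions state durations over an alternating
photoperiod (default 12 h) anchored at the light onset.

## Synthetic data generator

The generator exists so every stage can be validated against known truth
without any recording on disk. It emulates exactly the statistical
structure the analysis assumes:

* **States**: a first-order Markov chain over (AW, QW, NREM, REM) on the
  10-s epoch grid, row-stochastic, with direct wake→REM entries forbidden.
  The default matrix gives stationary occupancy ≈ 24/15/53/8%
  (AW/QW/NREM/REM), NREM bouts of a couple of minutes and REM bouts under
  a minute, with consolidated sleep episodes exceeding 5 minutes — a
  plausible mouse 24-h mix.
* **Background**: per channel, unit-variance 1/f^α Gaussian noise
  (α = 1, spectral shaping, flattened below 0.5 Hz), scaled to 30 µV.
* **State spectra**: a per-state background gain plus narrowband Gaussian
  components. Defaults were calibrated once, analytically, against the
  thresholds the states must realize (the log window-power SD of the 1/f
  background is ≈ 0.2 in 1–2 s windows): NREM carries ≈ 2.2× QW wideband
  power and ≈ 3.7× delta (gain 1.21 plus a 2 Hz delta component) —
  comfortably above the sustained 1-z staging criterion, cleanly
  separable from quiet wake at the epoch level, and still only ≈ 2.6 z
  on the session-wide ictal scale (threshold 4); REM carries strong
  7.5 Hz theta over a damped background (gain 0.7, theta component at 2×
  background variance), putting the raw theta/delta ratio near 6; AW has
  mild theta. Optional 10–15 Hz spindle bursts in NREM are off by
  default. Narrowband components are synthesized per state interval
  (states are hard-gated at epoch boundaries either way).
* **Spikes**: state-conditional Poisson events (defaults 30/h in REM,
  5/h in NREM, none in wake, matching the disease phenotype of interest),
  thinned to a 500 ms minimum separation so the detector's 200 ms
  refractory merge cannot fuse two true events. The waveform is a
  biphasic Gaussian-derivative pulse — the analysis constrains only
  duration and amplitude, so the shape is a generator-only choice —
  with total width 40 ms (≤ 75 ms contract) and peak scaled to 12 z of
  the local (±1 s) baseline SD. Amplitude is parameterized in z-units
  throughout because no physical spike amplitude is assumed. A
  configurable fraction of events appears on only 3 of 4 channels.
* **Artifacts**: monophasic fast-rise/exponential-decay transients on
  all channels with ±25 ms per-channel latency jitter and 8–14 z
  amplitude — they pass the per-channel amplitude screen but fail the
  biphasic/coherence test at the cluster-centroid level, which is what
  the template stage exploits.
* **Velocity**: 10 Hz (video frame rate), near-zero tracker jitter
  outside movement; within AW intervals, alternating movement bouts with
  off-gaps capped at 2.5 s so every AW epoch carries > 3 s of movement.
* **Seizures**: optional broadband amplitude surges (additive noise at a
  configured z relative to local background, 0.5-s cosine ramps) at
  configured times, on all or selected channels.

Identical config and seed give bit-identical outputs; all randomness
flows from one `numpy` Generator.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: volume conduction and inter-channel
correlation (channels are independent noise), electrode drift and slow
impedance changes, real artifact diversity (chewing, grooming,
electrical line noise), spindle/sharp-wave microstructure, gradual state
transitions (states switch instantaneously on the epoch grid), and
physiologically realistic spike waveform variability. Detector and
staging performance on real recordings must be validated against manual
review; the suite establishes correctness of the rules, not field
sensitivity/specificity.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for a single CPU: the detector
recovery experiment uses a 1-h recording at the native 2000 Hz; staging
accuracy uses a 2-h session; the state-conditional rate-recovery
experiment simulates 10 h at 500 Hz — rate estimation and Poisson
standard errors are independent of the sample rate, and 500 Hz retains
> 12 samples per spike width. Tolerances follow from the statistics
involved: exact assertions for rule outcomes and oracle equivalences
(1e-9 where floating point allows), 3 standard errors for stochastic
recoveries (Poisson rates, chain occupancy, flat-spectrum and flat-PETH
nulls), 1% for Parseval. Stochastic tests are seeded; seeds were chosen
for fixture validity (e.g. all four states present in a short session),
never to tune a measured quantity toward a bound.

Degenerate inputs fail loudly rather than silently: zero-variance
baselines, missing quiet-wake references, empty REM sets, upsampling
requests, unknown hypnogram labels (with the offending row named), and
events outside the hypnogram span are all errors.

## Known limitations

* The 3-of-4-channel coincidence requirement assumes all four electrodes
  are functional; a dead channel halves the margin.
* The movement criterion uses total supra-floor time per epoch, not the
  longest consecutive run; these differ for highly intermittent movement.
* The sustained-wideband criterion evaluates 1-s subwindows within each
  epoch independently; a power run straddling an epoch boundary can be
  missed in both epochs.
* Window-quantized seizure boundaries are only ±2 s accurate; the
  3-window (6 s) realization of the 5-s minimum slightly under-detects
  5–6 s events that straddle window edges.
* Session boundaries for multi-day recordings are not modeled; each file
  is treated as one session for standardization.
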