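# Methods

This document defines the analysis model implemented by `axonflow`, the
default parameters, and the rationale for each choice. All defaults live in
`AnalysisConfig` (analysis) and `SimulationConfig` (synthetic data); every
one can be overridden.

## Data model

* An **electrode layout** is the set of planar electrode positions (µm)
  routed beneath one microchannel, with a nominal pitch (default 17.5 µm).
* A **spike table** holds `(electrode_id, time_s, amplitude_uv)` rows with
  strictly increasing times per electrode and a recording duration. The
  canonical on-disk order sorts by time, then electrode id, with the most
  negative amplitude first among exact ties.
* A **microchannel spec** gives entry/exit coordinates, the member
  electrodes, the channel length (which must equal the entry–exit
  distance) and the kind, `straight` or `directional`.
* Files are versioned (`format_version=1.0`): recordings as HDF5 (float32
  traces), spike tables and layouts as commented CSV with exact float
  round-trip, channel specs and configs as YAML. A *bundle* directory
  holds `recording.h5` and/or `spikes.csv`, plus `channels.yaml` and
  optionally `layout.csv` so spike-table-only bundles retain geometry.

## Spike detection

1. Noise is estimated per electrode as the trace RMS, or robustly as
   `median(|v|)/0.6745` (`robust_rms=True`) when large spikes would
   inflate the plain RMS.
2. Samples with `|v|` above `detect_threshold_rms = 3.5` times the noise
   estimate are grouped into contiguous excursions; each excursion yields
   one event at its extremum, signed by the trace value there.
3. Events closer than `isi_min_s = 1 ms` are pruned greedily from the
   earliest event onward, so surviving gaps are all >= 1 ms. This also
   collapses the secondary threshold crossing that the positive lobe of a
   biphasic waveform can produce.

Note on separability: at 3.5 sigma, Gaussian noise alone crosses threshold
at a per-sample rate that, at 20 kHz, produces excursions at a rate
comparable to physiological firing. Threshold detection therefore bounds
the *amplitude* error of detected events, not the false-positive rate on
pure noise; downstream analyses (pairing, quartile rates) are designed to
be robust to a uniform background of false events because such events are
uncorrelated across electrodes.

## Channel geometry

Electrode positions are projected onto the entry-to-exit axis. The axial
*fraction* is the projected position divided by the channel length; the
*offset* is the orthogonal distance to the axis. The analysis band keeps
electrodes with offset <= `band_half_width_um = 17.5` (one pitch,
inclusive) and a fraction strictly inside (0, 1), so the endpoint
electrodes themselves are never intermediaries. Axial bins are half-open,
`[i/n, (i+1)/n)`, with fraction 1.0 assigned to the last bin.

## Propagation analysis

* **Pairing.** For each entry (source) event, the earliest unused exit
  (target) event with latency in the closed window
  `latency_window_s = [1 ms, 2 ms]` is claimed (greedy, two-pointer). The
  window matches sub-millimetre channels at physiological conduction
  velocities while excluding electrical crosstalk (near-zero latency) and
  chance coincidences. A channel orientation *qualifies* with
  `min_paired_events = 30` pairs, enough that a velocity fit is stable
  and chance qualification from independent Poisson activity is
  negligible at the rates and durations used.
* **Intermediaries.** For each anchor fraction (0.25, 0.50, 0.75), the
  band electrode whose spikes co-occur with more than
  `min_cooccurrence = 0.80` (strict) of the paired events — within the
  same latency window after the source event — and which lies closest to
  the anchor is selected; ties break on the smaller electrode id.
* **Latency trace.** For each selected electrode, the per-event latency is
  the first of its spikes inside the window; the trace records the median
  across events, with the source (latency 0) and target endpoints
  included, and requires strictly increasing axial positions.
* **Velocity.** Ordinary least squares of axial position (mm) on median
  latency (ms); the slope is the conduction velocity in mm/ms. The fit
  demands >= 2 points and nonzero latency spread, and a qualified
  orientation additionally requires a positive finite slope.
* **Classification.** Both orientations are analysed;
  `forward_only` / `backward_only` / `both` / `none` follows from which
  orientations qualify.

## Flux statistics

* Per-electrode firing rate = spike count / duration. Quartile means
  average electrode rates within each axial quartile (empty quartiles are
  an error — the layout does not cover the channel).
* **Flux ratio** = Q4 mean / Q1 mean. Undefined (NaN, flagged) when the
  Q1 mean is below 1e-6 Hz rather than silently infinite.
* The **binned profile** uses `profile_bin_fraction = 0.05` (5 % of the
  length, 20 bins) normalised by the Q1 electrode mean; empty bins are
  NaN.
* **Asymmetry test**: two-sided Mann–Whitney U between Q1 and Q4
  electrode rates, exact when both n <= 12 and tie-free, otherwise the
  normal approximation with tie correction; `alpha = 0.05`. Condition
  summaries report percent significant channels, cross-condition
  Mann–Whitney tests on flux ratios, and optional Benjamini–Hochberg
  correction (off by default so single-channel decisions match the
  per-channel test).

## Neurite outgrowth

* Track velocity = (last - first position) / elapsed hours, requiring
  >= 2 observations; missing intermediate frames do not bias it.
* Outgrowth regression: per-hour median positions across tracks, ordinary
  least squares; reports slope (µm/hr) and R².
* **Traversal extent**: background = mean + 3 SD of the intensity in the
  distal `background_window_fraction = 0.05` of a reference profile
  (ideally from a condition where nothing crosses; self-referenced
  otherwise), requiring >= 5 samples. Extent = the largest axial position
  whose intensity exceeds background, as a percentage of channel length;
  0 if none does. The mean+3SD rule is the usual low-false-positive
  threshold for fluorescence above background.
* **Success rate**: percentage of channels with extent >=
  `full_crossing_threshold_pct = 95` — "full crossing" tolerating edge
  effects in the last bins.
* Group comparisons: pairwise Welch t tests (unequal variances) and
  Dunnett's test against a designated control when comparing several
  conditions to one control.

## Synthetic data generator

Randomness uses `numpy` `SeedSequence(seed, spawn_key=(stream, key))`
with fixed stream numbers (1 Poisson, 2 propagation, 3 rendering,
4 neurite) and per-electrode keys, so adding electrodes or stages never
reshuffles existing draws and every dataset is reproducible from one seed
below 2^31.

* **Layouts** place `floor(length/pitch) + 1` collinear electrodes at one
  pitch spacing; the channel spec endpoints coincide with the first and
  last electrode.
* **Spontaneous activity**: independent homogeneous Poisson trains per
  electrode. Directional channels fire at `proximal_rate_hz = 2.6`
  everywhere plus an extra exit-side population at rates summing to
  `distal_rate_hz = 5.1` over the distal `distal_extent_fraction = 0.5`
  of the channel, reproducing an exit-side rate excess from axons that
  accumulated there. Straight channels use a single uniform rate.
* **Propagating events** occur at `propagation_rate_hz = 1.0`; each event
  appears on every channel electrode with delay = axial distance /
  velocity, optional Gaussian jitter, and optional downstream dropout
  (the source event itself is never dropped). `velocity_um_per_ms` and
  `total_latency_ms` are mutually exclusive ways to set the speed
  (default 650 µm/ms, i.e. 1.4 ms over 910 µm). Straight channels inject
  events in both directions.
* **Raw rendering** (`render_raw`, default on; off for long spike-level
  simulations where 20 kHz traces would be gigabytes) places a 1 ms
  biphasic template — trough exactly at the table amplitude, default
  -60 µV — at the nearest sample, additively, over Gaussian noise of
  `noise_sd_uv = 5`. At 20 kHz the sample period quantises latencies to
  0.05 ms; 1.4 ms over 52 inter-electrode steps hits exact sample
  multiples at the quartile anchors, which is why the end-to-end velocity
  recovery is exact.
* **Neurite datasets** draw per-hour steps from
  `max(Normal(mean, step_sd_um), 0)` and accumulate them, capped at the
  channel length. The default `step_sd_um = 1.0` keeps zero-truncation
  negligible so cohort mean velocities equal the configured means; larger
  spreads bias realised growth upward and are available for robustness
  checks, not calibration. Final tip positions induce the intensity
  profile (50 a.u. per tip at or beyond each 5 µm bin).

## Problem sizes used in validation

* Velocity: 100 events over 26 s (render ~2 s); jittered recovery averaged
  over 20 seeds.
* Flux: 600 s spike-level simulations; straight-channel null averaged over
  50 seeds; empirical type-I error of the asymmetry test measured over
  1000 null channels (expected ~5 %, accepted 3.5–6.5 %).
* Neurite: cohorts of 90–200 tracks over 16 h; traversal simulations use
  96 h so a ~11 µm/hr condition crosses a 900 µm channel while a
  ~3 µm/hr condition stalls below mid-channel.

## Limitations

Synthetic data is idealised: stationary Poisson firing, identical spike
templates, linear conduction, independent noise, no bursting, electrode
drift, or overlapping units. The generator validates the analysis chain
and its statistics; it does not emulate every property of organoid
recordings. The detector is a plain threshold detector, not a spike
sorter: on real data its output is a multi-unit event stream, which is
the intended input of the propagation and flux analyses.
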