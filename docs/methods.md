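# Methods

`hfobench` builds fully synthetic, statistically controlled SEEG records and
uses them to measure what five published high-frequency-oscillation (HFO)
detectors can and cannot do. This note documents the models, the
calibrations, and the choices made where the design was genuinely open.

## Background model

Each simulated channel is a stable autoregressive (AR) process: Gaussian
white noise of standard deviation `gain` filtered by `1/A(z)`,
`A(z) = 1 + a_1 z^-1 + ... + a_p z^-p`. Models are fitted to baseline
segments with the autocorrelation (Levinson–Durbin) method — the classic
LPC route — after mean removal; per-segment fits of one channel are averaged
coefficient-wise, with radial pole shrinkage to modulus 0.98 if the average
happens to be unstable (coefficient averaging does not preserve stability;
the smallest order where this can occur is 3). Synthesis discards a burn-in
of `10 × order` samples, so every realization is stationary from sample 0.

Default order is 30 at 2048 Hz: enough to carry the 1/f-like slope, a
rhythm or two, and the high-frequency noise floor. The floor matters: the
two built-in channel families are constructed by fitting an AR(30) (exact
Yule–Walker on the target autocorrelation) to a pole-placement spectrum
*plus* a flat noise floor pinned at the spectrum's ~450–500 Hz level. An
all-pole cascade without the floor collapses above the band, which no real
recording does — and which breaks time–frequency normalization there (see
below).

Two families are provided:

* `low_hf_model` — 1/f-like channel: log–log slope ≈ −3 over 10–500 Hz
  (two real poles near DC, weak 120 Hz resonance). This is the "ordinary"
  bipolar SEEG background.
* `high_hf_model` — semi-continuous high-frequency (SCHF) channel: a sharp
  140 Hz resonance (pole modulus 0.975, decay ≈ 20 ms — a sustained,
  visible ripple-band rhythm) plus a secondary 320 Hz resonance (0.965), so
  the whole 80–500 Hz band is elevated, the way mesial-temporal SCHF
  channels are.

## Event dictionary

The default dictionary is fully parametric: per channel, 8 ripples (centre
frequencies 90–220 Hz), 8 fast-ripples (260–450 Hz) and 8 spikes (widths
40–120 ms). HFO templates are Tukey-tapered (25% taper) sinusoids with mild
random amplitude modulation (depth ≤ 0.4) and frequency glides (±1
semitone), at 4.5–9 cycles; parameters are re-drawn until the atom passes
its own invariants (zero mean, ≥ 80% of energy inside its nominal band —
few-cycle atoms at a band edge can spill out). Spikes are area-balanced
differences of Gaussians: a narrow positive lobe whose width shrinks with a
`sharpness` parameter, followed by a broad slow wave; unit peak, zero mean.

Events can also be extracted from real traces by discrete-wavelet
coefficient masking (`dwt_mask_reconstruct`): forward DWT (orthogonal
Daubechies, periodization mode, default `db4`), zero everything outside the
mask, invert. The full mask reconstructs perfectly; any sub-mask is linear
and energy-contracting.

Band powers — the currency of the SNR definition — are measured with an
ideal zero-phase frequency-domain band-pass (zero-padded 2×, brick-wall
mask). An IIR/FIR measurement filter would attenuate templates sitting near
the 80 or 250 Hz edges and bias their SNR.

## Simulation generator

Event timings are a homogeneous Poisson process at the summed class rate
(default 3/min for each of the seven classes: Spk, Spk-R, Spk-FR, Spk-R-FR,
R, FR, R-FR); arrivals within 500 ms of another event or within 1 s of the
record edges are re-drawn, keeping the 100 ms scoring windows disjoint.
Class labels are drawn proportionally to the configured rates.

Every HFO component is scaled so its band power over its own support sits
exactly `snr_db` above the clean background's power in the same band (same
measurement filter for both; the HFO SNR is fixed per realization). Spikes
draw an independent uniform SNR in 0–15 dB referenced to broadband (1–500
Hz) power, a uniform time-stretch k in 0.8–1.25, and multiply the
background by a post-spike silencing notch (Tukey-edged dip to 1 − depth,
default depth 0.5, spanning the stretched spike support). HFOs co-occurring
with a spike or another HFO get an independent uniform timing jitter of
±20 ms. Background band powers are measured before any insertion, so the
SNR contract is exact for isolated events and all-zero rates reproduce the
plain background sample-for-sample.

All randomness descends from one master seed through named
`SeedSequence` substreams (background / timeline / event draws), so records
are bit-reproducible.

## Detectors

The four time-domain detectors share a zero-phase FIR band-pass front-end
(80–500 Hz, Kaiser design, ≥ 60 dB stopband). Parameters are the
defaults of the published implementations, frozen as dataclass fields:

* **STE** — 3 ms moving RMS; threshold mean + 5 SD of the RMS trace;
  candidates merged across < 10 ms gaps, kept if ≥ 6 ms (3 periods of a
  500 Hz oscillation) and containing > 6 rectified peaks above
  mean + 3 SD.
* **SLL** — first-order backward difference, band-pass, line-length energy
  over a 12 ms window; threshold = 97.5th percentile of the record's own
  energy distribution; detections ≥ 12 ms. The line length of a
  differenced signal is identically a windowed |second difference|, whose
  |1 − e^{−jω}|⁴ = 2(3 + cos 2ω − 4 cos ω) gain over-expresses the
  fast-ripple band.
* **HIL** — Hilbert envelope of the band-passed signal; threshold
  mean + 5 SD of the whole-record envelope (a `pure_sd` flag gives the bare
  5 SD reading); supra-threshold runs ≥ 10 ms.
* **MNI** — two stages. Stage 1 scans 125 ms windows and computes the
  wavelet entropy (WE) of each window's biased autocorrelation on one scale
  per octave through the band (80/160/320 Hz); windows above a threshold
  fraction of the theoretical maximum `log10(3)` are baseline. With enough
  baseline (≥ 15% of windows) the energy threshold is the 99.9999th
  percentile (numpy linear interpolation, effectively the maximum order
  statistic) of baseline RMS; otherwise an STE-like threshold is
  re-estimated iteratively after deleting detected stretches (≤ 10
  iterations, 0.5% relative tolerance).
* **Delphos** — no band-pass. Analytic Morlet transform (ω₀ = 6, 12
  voices/octave, 10–800 Hz) of the raw signal; each frequency row is
  z-scored by a Gaussian fitted to its real coefficients within Tukey's
  range (quartiles ± 1.5 IQR), the SD corrected for the ±2.698σ truncation
  (factor 0.9710, derived from the truncated-normal variance). Local maxima
  of the normalized energy (z_re² + z_im²)/2 above 30 are characterized by
  half-height time width and frequency spread and classified: oscillation
  if the spread matches a pure tone's and the width exceeds a Dirac
  impulse's; spike for the converse. Only oscillation detections with peak
  frequency in 80–500 Hz enter HFO scoring.

Delphos calibration and measurement details that the design left open:

* Reference responses are self-calibrated per (fs, grid): the transform of
  a unit impulse gives per-row Dirac time widths; transforms of grid-tones
  give full cross-row tone profiles. At detection time the tone profiles
  are divided by the record's per-row background power, because the
  normalized map tilts every blob toward higher frequencies (background
  power falls with frequency) and the reference must tilt with it.
* A half-height run that touches the grid edge has uncertifiable spread and
  is treated as unbounded; the grid therefore extends to 800 Hz — about
  2/3 octave of headroom above the scoring band — so fast-ripple blobs are
  not clipped.
* The reported peak frequency is the raw-energy argmax within the blob's
  row run (the normalized peak sits systematically ~1 row high).
* Duplicate-suppression around an accepted peak covers only ±4 rows of its
  half-height run: a distinct structure at a different frequency (an
  oscillation beneath a broadband transient ridge) must stay detectable.

The first and last 0.5 s of every record are excluded from detection in all
five detectors (filter and wavelet edge effects).

## Wavelet entropy normalization

WE is computed from constant-shape Morlet kernels applied to the biased
autocorrelation, with each scale's power referenced to the response the
same kernel gives to band-limited white noise (its in-band area). Without
that reference, kernel bandwidth and the band-pass edges skew the scale
distribution even for a flat spectrum; with it, band-limited white noise
scores ≈ log10(|A|) (measured 0.97 of the maximum) and a pure tone scores
≈ 0. WE remains PSD-dependent by construction — that is the point the
benchmark demonstrates: the 1/f channels put 25–28% of their windows above
0.55 × maximum while SCHF channels put only 7–11%, so the MNI mode switch
(threshold fraction 0.55, minimum baseline share 0.15, both calibrated on
the two synthetic families) selects baseline mode exactly on the 1/f
channels. The published threshold values for this stage are not stated
numerically anywhere, and any usable value depends on the WE
implementation; ours are package calibrations.

## Evaluation

A 100 ms confidence interval (CI) is centred on each inserted HFO
component at its actual (jittered) time; inserted pure spikes get no CI, so
spike-triggered alarms cost precision. A detection matches a CI by interval
overlap; the assignment maximizes the number of matched CIs (maximum
bipartite matching — verified against exhaustive enumeration on small
instances), each matched CI counts once as TP, unmatched CIs are FN,
detections overlapping no CI are FP, and surplus detections inside an
already-matched CI are neither. Sens = TP/(TP+FN), Prec = TP/(TP+FP), F =
their harmonic mean; 0/0 cases are reported as missing rather than imputed.
Per-class sensitivity treats composite classes per component (Spk-R-FR
contributes one R and one FR CI).

## Problem sizes

The compact benchmark grid used by the test suite is 4 channels (two per
family) × {0, 5, 10, 15} dB × 3 realizations of 120 s; the acceptance
script uses 5 realizations, and a `paper`-scale profile (8 × 4 × 30 × 600
s) is available for full-scale runs. The reported headline behaviors
(Delphos precision 1 with zero false positives at every SNR, monotone
sensitivity in SNR, STE/HIL threshold inflation ≈ +35% from 0 to 15 dB
versus ≈ +7% for SLL's percentile threshold, ripple-favoring class
asymmetry for STE/HIL/MNI) were measured on the 5-realization grid.

## Known limitations

* Synthetic spikes and tapered-sinusoid HFOs lack the waveform diversity of
  extracted patient events; passing benchmarks here demonstrate the
  machinery and the detectors' structural biases, not clinical performance.
* The SCHF family concentrates its rhythm in the ripple band (that is what
  keeps its wavelet entropy low); at fixed per-band SNR this makes ripple
  events on those channels absolutely louder, which narrows or inverts the
  fast-ripple advantage the line-length detector shows on 1/f channels
  (isolated events at 10 dB: FR 1.00 vs R 0.92) once results are pooled
  across families.
* Backgrounds are single-channel and stationary; no line noise, artifacts,
  or spatially correlated noise.
* The evaluation counts a spike-triggered detection inside an HFO's CI as a
  true positive (the CI rule has no way to know why the detector fired);
  at 0 dB, where HFOs are invisible, this floor effect dominates measured
  sensitivity for the amplitude detectors and can exceed their 5 dB value
  by a fraction of a percent.
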