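# Methods

## Overview

`psgpipe` re-implements a classical rodent polysomnography analysis as a
fully testable pipeline. Because licensed animal recordings are not
shippable, the package is driven by its own synthetic polysomnography
generator: a semi-Markov vigilance-state model with per-state spectral
signatures. The generator's ground truth makes every downstream stage —
spectral feature extraction, rule-based staging, architecture metrics,
group statistics — verifiable end to end.

## Signal model and feature extraction

EEG is sampled at 125 Hz, EMG at 250 Hz; both channels pass through
zero-phase Butterworth band-pass filters matching the acquisition
front-end (EEG 0.16–53.05 Hz; EMG 0.72–112.88 Hz, both below their
Nyquist frequencies). Scoring features are computed per 8-s epoch:

* **EEG band powers.** A 16-s FFT window centred on each epoch (hop 8 s,
  i.e. 50% overlap) is mean-detrended, Hann-tapered, and its one-sided
  periodogram integrated over delta (0.16–4 Hz), theta (6–9 Hz), sigma
  (10–14 Hz) and beta (14–32 Hz). Band membership is half-open
  (`lo <= f < hi`), so adjacent bands never share a bin; the band set
  deliberately leaves gaps at 4–6 and 9–10 Hz, which is why
  the four band powers sum to less than total power. The first and last
  epochs reuse the nearest fully valid window. The Hann taper is this
  package's leakage control; a rectangular window would rescale
  absolute powers but staging uses only relative comparisons.
* **EMG power.** 2-s FFT windows tile each epoch; 32–64 Hz power is
  integrated per window and the four sub-window values are averaged
  (robust to a single noisy sub-window, preserves units).
* **sigma\*theta**, the product of sigma and theta powers, is the EEG
  wake-vs-sleep discriminant.

## Staging rule and threshold fitting

Each epoch is scored wake (high EMG), NREM (low EMG, high sigma\*theta,
high delta) or REM (low EMG, high sigma\*theta, low delta). The
"high/low" cuts depend on each animal's electrode placement and gain,
so they are fitted per recording: a
two-component Gaussian mixture on the log power (EM, k-means
initialisation, fixed seed), cut at equal posterior between the modes,
with an inter-quartile midpoint fallback when the mixture degenerates
(mode separation `d < 0.5` pooled SDs, no posterior crossing, or EM
failure). The delta cut is fitted only on epochs already below the EMG
cut, because the NREM/REM delta contrast is defined within sleep.

Two documented choices where the rule text is ambiguous: EMG has
precedence (it is the wake discriminant), and low-EMG epochs whose
sigma\*theta is also low match neither sleep signature and are scored
as quiet wake — the conservative reading; their fraction is reported in
the fit diagnostics. The manual rescoring step of traditional scoring workflows is
non-algorithmic and out of scope; an optional run-length smoother
(`smooth_hypnogram`) is provided but off by default.

## Synthetic polysomnography

The generator inverts the staging rules into a generative model.

**State chain.** A semi-Markov chain emits dwells in long wake, brief
wake, NREM and REM (the two wake flavours share the WAKE output code).
Wake always yields to NREM; NREM exits to REM (p = 0.25), brief wake
(p = 0.35) or long wake (remainder); REM exits to wake (p = 0.6) or
back to NREM. REM is therefore reachable only from NREM, matching
rodent physiology. Dwells are log-normal, rounded up to whole 8-s
epochs: wake mean 180 s (log-sd 0.9), NREM mean 200 s (log-sd 1.0),
REM mean 64 s (log-sd 0.4), brief wake mean 16 s (log-sd 0.4). The
long NREM tail is deliberate: sleep-onset latency is defined through
NREM bouts longer than 300 s, so such bouts must be a routine feature
of consolidated sleep, and the heavy tail also reproduces the long-bout
end of the bout-duration histograms. Under these defaults the light
phase is roughly 55% NREM, 6% REM and the rest wake. Sleep pressure
switches at ZT 12: in the dark phase wake dwells stretch fivefold and
sleep dwells shrink (x0.7 NREM, x0.8 REM).

**Group presets.** Every record begins awake (the animal was just
handled). The cage-change (first-night-effect) preset draws the initial
wake dwell from an inflated distribution (mean 4000 s vs 600 s for
tail-handled controls; log-sd 0.5 so the manipulation, not tail noise,
dominates) and, for the first 4 h, lengthens wake dwells (x2.5),
shortens NREM dwells (x0.55) and suppresses REM entry (x0.25). The
probiotic-like arm shortens the initial wake dwell only (1200 s under
cage change). The antihistamine-like arm shortens REM dwells (x0.45),
suppresses REM entry (x0.4) and doubles the brief-wake branch (NREM
fragmentation), while moderating the cage-change wake effects (initial
wake 1500 s) — the phenomenology of an effective but REM-suppressing,
sleep-fragmenting hypnotic. All magnitudes were fixed from these
qualitative targets before the pipeline's recovery checks were run.

**Signals.** Per band, unit-RMS band-limited noise (zero-phase filtered
white noise) is multiplied by a per-epoch amplitude envelope and
summed, over a 1/f background (amplitude 0.25); EMG is 32–64 Hz noise
scaled by the state's EMG amplitude over a small white floor (0.05).
Envelopes cross-fade linearly over 0.5 s at epoch boundaries to avoid
spectral splatter. Default amplitudes (arbitrary units — no
amplifier gain is modelled): wake delta/theta/sigma/beta =
1.0/1.2/0.6/1.0 with EMG 3.0; NREM 4.0/1.5/1.5/0.5 with EMG 0.8; REM
0.8/3.0/1.2/0.6 with EMG 0.3. These encode the rule contrasts (NREM
delta dominant; wake EMG ≫ NREM ≥ REM; sigma\*theta higher in both
sleep states than wake) with wide margins, so staging on clean
synthetic data approaches 100% agreement; the integration tests
enforce the weaker round-trip guarantee of ≥95% agreement and ≥90%
REM recall. A 12-bit
uniform quantizer over a configurable full scale emulates a 12-bit
acquisition chain; it is off by default in tests.

**What the generator does not emulate.** No spindle/K-complex
morphology, no artifacts or electrode noise, no ultradian drift in
spectral content, no inter-animal amplitude variability beyond the
random draws. Passing round-trip tests therefore certify the pipeline's
internal consistency — that the staging rules recover exactly the
structure they presume — not its accuracy on real, artifact-laden
recordings, which is why traditional workflows keep a manual review
step.

## Architecture metrics

Episodes are maximal runs of one state. Metrics per analysis window
(half-open ZT intervals; epochs assigned by start time): state totals
(8 s per epoch), episode counts, bout-duration histograms (default
single edge at 300 s with an open top bin), ordered transition counts
and per-hour rates, NREM interruptions (wake episodes ≤ 64 s flanked by
NREM on both sides; the term is operational, so the cap is configurable and recorded in
output metadata), sleep latency
(time to the first NREM bout *strictly* longer than 300 s, i.e. ≥ 38
epochs, measured from the recording start; undefined latency is
reported censored at the window length so fully awake animals are not
dropped), hourly state totals, hourly relative NREM-delta power
(within-animal normalisation to the window's mean NREM delta, removing
amplitude nuisance) and REM accumulation (both the per-hour and the cumulative
series are emitted). Episodes
straddling a window edge are truncated for totals but counted once, in
the window containing their start, for counts and transitions.

## Group statistics

One-way ANOVA with Tukey's HSD, and two-way handling x treatment ANOVA
(Type-II sums of squares; identical to the classical decomposition on
balanced designs) with Bonferroni-corrected planned cell contrasts
(handling effect within each treatment, and each treatment against
vehicle within each handling level; each contrast is a t-test on the
residual mean square, p multiplied by the number of contrasts, capped
at 1). Zero-variance inputs are flagged "not tested" rather than
raising. Per-hour one-way tests are emitted uncorrected by default,
with an optional Bonferroni factor across hours. Normality and
homoscedasticity are not checked — a documented limitation of this
classical workflow.

## Numerical and scale choices

* Butterworth order 10 per edge, applied forward-backward; padding is
  several time constants of the lowest cutoff so the 0.16 Hz pole's
  transient stays out of the analysis.
* Determinism: all randomness flows from `numpy` `SeedSequence`; the
  per-animal stream is keyed by (run seed, cell index, animal index),
  so growing a cohort never reshuffles existing animals.
* Integration-test problem sizes: the staging round-trip runs the full
  six-cell, 48-animal, 8-h cohort; planted-effect recovery uses 40–100
  replicate cohorts of the four Veh/DIPH cells (hypnogram level — the
  effects live in the state sequence, and signal synthesis adds nothing
  to that check); calibration uses 1000 null replicates; the metric
  oracle suite uses 10^4 randomized hypnograms of 5–160 epochs against
  independent brute-force scans.

## Known limitations

* The stager assumes each recording contains enough of both sleep
  states for the mixtures to split; recordings that are almost entirely
  one state fall back to percentile cuts and are flagged in
  diagnostics.
* Latency under the cage-change preset retains a long right tail (the
  wait for a qualifying bout compounds the initial wake dwell), so
  small-cohort latency contrasts between the cage-change arms are
  noisy; the wake/NREM totals are the robust planted effects.
* EDF support writes 16-bit files readable by standard tools but omits
  annotations; reading requires `mne`.
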