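# Methods

This note documents the models behind `ecapmap`, the parameters that
matter, and what the synthetic data do and do not capture.

## The fitting problem

A cochlear-implant fitting map assigns each electrode channel an upper
stimulation bound (MCL, maximum comfortable loudness) and a lower bound
(THR, behavioral threshold), in the manufacturer's charge units (qu).
Throughout the toolkit, THR is fixed at 10% of MCL on active channels (the
clinical default), the processor volume defaults to 90%, and a 12-channel
array with at least 10 active channels is required for ECAP-based fitting.

Three maps are compared per virtual participant:

* **ClinMAP** — the everyday clinical map, taken as the reference;
* **LiveBurstMAP** — behaviorally fitted (per-channel loudness judgements
  with current bursts, balancing, global live adjustment);
* **LiveECAPMAP** — built from ECAP thresholds, then globally live-adjusted.

## ECAP trace model (`ecap_sim`)

One telemetry sweep is `artifact + response + noise` on a 1.7 ms window
sampled at 10 µs:

* artifact: `s · a · charge · exp(−t/τ)`, τ = 0.10 ms, with sign `s`
  flipping between anodic- and cathodic-leading pulses; the default scale
  `a` = 200 µV/qu dwarfs small responses, which is why polarity averaging
  matters;
* response: `A · [−g(t; 0.30 ms, 0.08 ms) + 0.7 · g(t; 0.60 ms, 0.08 ms)]`
  with unit-peak Gaussian bumps `g` — an N1 trough and a smaller P2 peak at
  typical ECAP latencies — and drive `A = slope · max(0, charge − t_i)`:
  linear growth above the channel threshold `t_i`, nothing below, nothing on
  non-responsive channels.  The 0.7 P2/N1 ratio is fixed so the
  peak-to-peak amplitude stays proportional to `A` (factor 1.7);
* noise: i.i.d. Gaussian, default 5 µV RMS per sweep.

A standard measurement averages 14 sweeps (7 per leading polarity): the
artifact cancels exactly in the mean and the noise drops to
`5/√14 ≈ 1.34 µV`.  The 60 Hz figure is the stimulus presentation rate; it
enters only the fitting-duration accounting, not trace content.

### Virtual patients

Per-channel ECAP thresholds are drawn smoothly along the array (linear
interpolation between four uniform control points in [1, 4] qu plus 3%
jitter); growth slopes are independent uniform in [20, 100] µV/qu.  The
true comfortable-loudness profile is **derived from the threshold
profile**: the same mean-anchored attenuation used by the map builder
(retaining 42% of the relative variation), scaled to an overall level
uniform in [12, 25] qu, with 5% independent per-channel jitter.  This
encodes the clinical premise on which ECAP-based fitting rests — MCL
profiles are flatter than, but correlated with, threshold profiles — and
guarantees clinical MCLs above 5.5 qu, so initial ECAP maps (capped at
5 qu) are always quieter than the clinical map.  Channel jitter is the
*irreducible* mismatch between an ECAP-derived and a behavioral profile in
this model; with it at 5%, simulated cohorts produce map contrasts Δ_MAP of
a few percent, the regime the evaluation layer is designed to resolve.

### Behavioral burst fit

Burst MCLs are `true_mcl · (1 + ε)` with behavioral judgement noise
`ε ~ N(0, 0.08²)`.  Loudness balancing against the medial reference channel
(E06, or the nearest active channel) mixes each channel's *relative* error
toward the reference's: `ε_i ← 0.8·ε_i + 0.2·ε_ref`.  Balancing operates in
error space deliberately: balancing is a correction applied to perceived
loudness deviations, and a noise-free behavioral fit must reproduce the true
profile exactly, which raw-level mixing toward E06 would violate.  Global
live adjustment uses the patient gain rule below.  The behavioral fitting
duration is lognormal with median 9 min (adults) or 7 min (children) and
log-sd 0.25, matching the clinical ordering FD_ecap < FD_burst.

### Live adjustment gain

Feedback-driven global loudness adjustment is modeled as
`gain = median over active channels of true_mcl_i / mcl_i`: the listener
scales the whole map to comfortable loudness; the median makes the rule
robust to single-channel profile mismatch.

## Measurement chain (`agf`)

Preprocessing: the first 0.15 ms is blanked (zeroed samples), the trace is
amplified 100x and low-pass filtered at 5 kHz (4th-order Butterworth,
forward-backward, zero phase).  The N1–P2 amplitude is
`max(0, max over [0.45, 0.9] ms − min over [0.2, 0.45] ms) / 100`, reported
at input scale.  The filter passes the response bumps with ≈ 2–3%
attenuation; the amplitude metric therefore grows as ≈ 1.66·slope per qu
above threshold, and the x-intercept — the quantity of interest — is
unaffected by this pure slope change.

AGF acquisition sweeps 0.5 → 6 qu in 0.1 qu steps (56 levels), one
averaged measurement per level.  The noise floor is the robust sd
(1.4826·MAD) of the amplitudes at the lowest five levels; these lie below
the population's minimal threshold (1 qu), an assumption of the default
sweep, not a general guarantee.

### Threshold estimation

The N1–P2 metric of pure noise has *positive* mean (a max minus a min), so
both a floor offset and a floor spread exist.  A point is supra-noise when
its amplitude exceeds the baseline median by more than 3x the noise floor;
the fit uses the contiguous supra-noise run ending at the highest level
(isolated baseline excursions would otherwise enter the regression and drag
the intercept down — with only five baseline levels the MAD floor is
occasionally underestimated, and an unguarded 3x-floor criterion then
admits the whole sub-threshold plateau).  The baseline median is also
subtracted from the fitted amplitudes so the extrapolation target is the
true zero of the neural response.  A threshold is **found** when ≥ 4
supra-noise points exist, the fitted slope is positive, R² ≥ 0.8, and the
intercept lies within (0, max level].  These criteria are conventional
evoked-potential practice, declared stand-ins for the clinical software's
unpublished rule.  Measured performance at default settings (200 channels,
5 µV noise): bias ≈ +0.01 qu, mean |error| ≈ 0.012 qu; the false-found
rate on response-free channels is ≤ 2%.

## Map builder (`artfit`)

Quick mode measures channels in the fixed order E10, E06, E03, E12, E07,
E02, E09, E05, E01, E11, E08, E04 — cycling basal → medial → apical so the
first four span all sections — substituting a disabled channel by the
nearest free active channel in its section (basal side preferred on ties),
and stops once four thresholds are found.  Unmeasured channels are filled
by linear inter-/extrapolation over the channel index (constant for a
single found threshold), clipped at 0.1 qu.  The completed profile is
flattened about its mean, `f_i = m + 0.42·(t_i − m)`, which preserves the
mean and retains exactly 42% of the peak-to-peak variation, then scaled so
the maximum active MCL is exactly 5 qu.  The fallback — all active MCLs at
5 qu — triggers when fewer than 3 thresholds are found or the found
channels are not spatially well distributed (fewer than two sections
covered, or an index span below 6 positions); 3 is the minimum that anchors
interpolation plus two-sided extrapolation.  Whether the 5 qu cap applies
pre- or post-flattening is ambiguous in principle; it is applied
post-flattening, matching the construction order above.

Fitting duration is simulated accounting, not wall clock: 14 curves at
60 Hz per averaged measurement (≈ 0.23 s), 20 s setup per measured channel,
60 s for live adjustment — ≈ 3.2 min for a four-channel run, reproducing
the ordering FD_ecap < FD_burst.

## Evaluation layer (`evalstats`)

Implements the deviation quantities and margins exactly as defined
(per-channel RD in percent with the clinical MCL as reference, map-level
means, Δ contrasts; 20% map margin, 10% duration margin, 2 dB SRT margin).
Channels with zero clinical MCL are excluded with a warning rather than
producing infinities.  Paired comparisons screen the differences with
Shapiro–Wilk *and* Lilliefors at α = 0.05; only if both pass is the paired
t-test used, otherwise the two-sided Wilcoxon signed-rank test
(zero-discarding; all-zero differences report p = 1).  Measured type-I
error at n = 22 is within 5% ± 2%.  The sample-size formula is the
one-sided normal approximation `n = ⌈((z_{1−α} + z_{power})·σ/δ)²⌉`,
which yields n = 22 for both study endpoints (margin 20%, σ 37.63%; margin
1.17 min, σ 2.16 min) at α = 0.05, power 0.80; a t-based iterative variant
is available (`use_t=True`).  Pooled correlations use raw
(participant, channel) pairs; per-participant averaging can be done by the
caller before pooling.

## Speech-test simulator (`srt_sim`)

The listener's word-correct probability is logistic in SNR,
`p = 1/(1 + exp(−4·slope·(snr − srt)))`, normalized so the slope at the 50%
point equals `slope` (default 0.15/dB).  The effective SRT couples map
quality to performance: `srt50_base + map_sensitivity · RMS` of the relative
MCL deviation from the clinical map (default sensitivity 10 dB per unit
RMS, so a uniform 20% misfit costs 2 dB).  This linear coupling is a
modeling choice motivated by the documented link between channel loudness
imbalance and poorer speech perception; sensitivity 0 recovers a
map-independent listener for null testing.

The adaptive list presents 14 sentences of 5 words at a fixed 65 dB SPL
speech level; after each sentence the SNR moves by
`−step · (prop_correct − 0.5)/0.5`, with the step shrinking geometrically
from 4 dB to a 1 dB floor at each direction reversal of the track.  The
reversal-driven shrink (rather than a per-sentence schedule) is required by
the protocol: training starts at +20 dB SNR, and a schedule reaching its
floor within a few sentences cannot travel the ≈ 20–25 dB to the threshold
in a 14-sentence list, which would bias training SRTs upward by ≈ 2 dB.
The SRT estimate is the mean presented SNR over the last 8 sentences.
Measured recovery at default slope: mean absolute error ≈ 0.45 dB, sd
≈ 0.55 dB over 500 lists.  The protocol runs two training and two test
lists per map for adults (one each for children), with test start at the
average training SRT + 10 dB and pseudo-randomized map order.  Sentence
count, word count, and step constants are configuration defaults, not
facts about the clinical test material.

## What the synthetic data do not capture

* No biophysical nerve model: no refractoriness, no masker-probe paradigms,
  no saturating (sigmoidal) growth — the AGF is exactly linear above
  threshold, so threshold recovery here is easier than on real nerves with
  plateaus or non-monotonic growth.
* The comfortable-loudness profile is *constructed* to follow the flattened
  threshold profile; real MCL/ECAP correlations are weaker and more
  variable.  Passing non-inferiority in simulation therefore demonstrates
  the machinery, not clinical performance.
* The SRT link to map deviation is a smooth RMS penalty; real speech
  perception depends on which channels deviate and in which direction.
* No acoustic signal processing, no real sentence material, no impedance
  model beyond the active-channel flags; charge stays in opaque qu with no
  conversion to nC.

## Numerical choices

* THR/MCL validation tolerance 1e−9; serialization round-trip tolerance
  1e−12; amplitudes below 1e−12 µV snapped to zero to absorb filter
  round-off.
* Profile completion clips thresholds at 0.1 qu; scaling requires a
  positive profile maximum.
* Ties in schedule substitution resolve to the basal side, then the lower
  index; the reference channel for balancing is the active channel nearest
  E06.
* All randomness flows through explicit `numpy.random.Generator` objects;
  patients are reproducible from a single integer seed.
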