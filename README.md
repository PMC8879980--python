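# ecapmap

Simulation and evaluation toolkit for **ECAP-based initial fitting of
cochlear implants**.

A cochlear implant (CI) must be *fitted*: for each of the 12 channels of a
MED-EL style electrode array, an audiologist sets the maximum comfortable
loudness level (MCL) and the behavioral threshold (THR) that bound the
electrical stimulation.  Behavioral fitting needs reliable feedback from the
listener — a problem for toddlers and others who cannot provide it.  An
alternative is to build the initial map from an *objective* measure: the
electrically evoked compound action potential (ECAP), the auditory nerve's
synchronized response to a current pulse, recorded through the implant's own
telemetry.

`ecapmap` implements that pipeline end to end on **synthetic virtual
patients**, so the whole measurement-and-fitting chain can be exercised,
tested, and evaluated without hardware or clinical data:

* **`ecapmap.ecap_sim`** — virtual patients (per-channel ECAP thresholds
  t_i, growth slopes, a comfortable-loudness profile, a psychometric
  listener) and raw telemetry traces: polarity-flipping stimulation
  artifact + N1/P2 response + noise.  Averaging 7 anodic-leading and
  7 cathodic-leading sweeps (14 curves) cancels the artifact.
* **`ecapmap.agf`** — the measurement chain: blanking, 100x amplification,
  5 kHz zero-phase low-pass, N1–P2 amplitude extraction, fine-grained
  amplitude growth function (AGF) acquisition, and automatic threshold
  estimation as the x-intercept of the linear supra-threshold segment:
  amp(s) ≈ k·(s − t), so t = −intercept/slope of the fitted line.
* **`ecapmap.artfit`** — the map builder: quick-mode scheduling (≥ 4
  channels alternating basal/medial/apical), linear inter-/extrapolation to
  complete the threshold profile, *flattening* toward the mean so only 42%
  of the profile's variation remains (f_i = m + 0.42·(t_i − m)), scaling so
  the maximum initial MCL is exactly 5 qu, a flat-map fallback when too few
  thresholds are found, and global live-mode loudness adjustment.
* **`ecapmap.maps`** — the fitting-map data model (MCL/THR/active/volume),
  validation (THR = 10% of MCL on active channels, volume 90%), the ≥ 10
  active channels eligibility rule, and JSON serialization.
* **`ecapmap.evalstats`** — evaluation mathematics: per-channel relative
  deviations RD = |(MCL_clin − MCL_x)/MCL_clin|·100, their contrasts
  Δ_MCL / Δ_MAP against a 20% non-inferiority margin, the fitting-duration
  saving Δ_FD = 100·(FD_burst − FD_ecap)/FD_burst against a 10% superiority
  margin, SRT contrasts against a 2 dB margin, pooled Pearson r², paired
  t / Wilcoxon dispatch behind a double normality screen (Shapiro–Wilk +
  Lilliefors), t-based confidence intervals, and the one-sided one-sample
  sample-size formula n = ⌈((z_{1−α}+z_{power})·σ/δ)²⌉.
* **`ecapmap.srt_sim`** — an adaptive speech-reception-threshold (SRT50)
  simulator: logistic psychometric listener, reversal-shrinking staircase at
  fixed 65 dB SPL speech level, training at +20 dB SNR, tests starting at
  the training SRT + 10 dB.

## Worked example

```python
import numpy as np
import ecapmap as em
from ecapmap import srt_sim

patient = em.make_virtual_patient(seed=1)
clin = em.clin_map_of(patient)            # the everyday clinical map
rng = np.random.default_rng(1)

ecap, diag = em.build_ecap_map(patient, rng=rng)          # ECAP-based initial map
live_ecap, fd_ecap = em.live_adjust_ecap(ecap, patient, diag.fd_minutes)
live_burst, fd_burst = em.burst_fit(patient, rng)         # behavioral comparator

comp = em.map_comparison(em.channel_deviations(clin, live_ecap, live_burst))
dc = em.duration_comparison(fd_ecap, fd_burst)
srts = srt_sim.training_then_tests(patient.listener, clin, live_burst,
                                   live_ecap, np.random.default_rng(2))
sc = em.srt_comparison(srts["ClinMAP"], srts["LiveECAPMAP"], srts["LiveBurstMAP"])
```

Output:

```
measured channels: ['E10', 'E06', 'E03', 'E12']  thresholds found: 4
initial map max MCL: 5.0 qu  (fallback: False)
RD_ecap_MAP = 7.12%  RD_burst_MAP = 3.52%  Delta_MAP = 3.60%
FD_ecap = 3.20 min  FD_burst = 7.18 min  Delta_FD = 55.4%
SRT clin/ecap/burst = -0.98 / 0.87 / -0.01 dB SNR  Delta_SRT = 0.89 dB
non-inferior (20% map margin): True   non-inferior (2 dB SRT margin): True
```

Reading: quick mode measured four channels spanning all array sections and
found a threshold on each, so no fallback was needed and the initial map
peaks at the safe 5 qu ceiling.  After live adjustment, the ECAP-based map
deviates from the clinical map by 7.1% on average versus 3.5% for the
behavioral map — a contrast of 3.6%, far inside the 20% non-inferiority
margin — while taking less than half the fitting time.  The simulated
speech test shows the ECAP-based map costing 0.89 dB relative to the
behavioral map, inside the 2 dB margin of clinical relevance.

## Command line

```sh
ecapmap simulate --seed 5 --n-patients 3 --out patients/
ecapmap fit --patient patients/patient_000005.json --mode artfit --seed 1 \
        --out ecap.json --diagnostics diag.json
ecapmap fit --patient patients/patient_000005.json --mode burst --seed 2 --out burst.json
ecapmap validate ecap.json
ecapmap adjust --gain 1.5 ecap.json louder.json
ecapmap agf --patient patients/patient_000005.json --channel E06 --out agf.csv
ecapmap evaluate --clin clin.json --ecap ecap.json --burst burst.json --out metrics.csv
ecapmap srt --patient patients/patient_000005.json --maps clin.json burst.json ecap.json \
        --seed 3 --out srt.csv
```

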