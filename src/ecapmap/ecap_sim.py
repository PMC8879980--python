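"""Synthetic-data generator: virtual patients and raw ECAP telemetry traces.

The electrically evoked compound action potential (ECAP) is the synchronized
auditory-nerve response to a biphasic current pulse, recorded through the
implant's own telemetry.  A raw recording is the sum of three components:

* a *stimulation artifact* that decays exponentially after the pulse and
  flips sign with the leading polarity of the pulse (anodic-first vs
  cathodic-first) — the basis of artifact rejection by polarity averaging;
* the *neural response*, modeled as a negative N1 trough followed by a
  positive P2 peak (two Gaussian bumps), whose amplitude grows linearly with
  stimulus charge above the channel's ECAP threshold and is zero below it;
* additive Gaussian recording noise.

Averaging seven anodic-leading and seven cathodic-leading sweeps (14 curves
in total, the clinical default) cancels the artifact exactly in expectation
and reduces the noise standard deviation by sqrt(14).

A :class:`VirtualPatient` bundles the physiological ground truth that the
measurement chain tries to recover (per-channel ECAP thresholds and growth
slopes), the behavioral ground truth that fitting tries to match (the true
comfortable-loudness profile), and a psychometric listener model for the
speech-test simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .maps import (
    DEFAULT_VOLUME,
    N_CHANNELS,
    ElectrodeLayout,
    FittingMap,
    channel_label,
    global_adjust,
    set_thr_from_mcl,
)
from .srt_sim import ListenerModel

# Trace geometry and morphology constants.  The paper-grade recording chain
# works at a much higher internal sampling rate than the 60 Hz stimulus
# repetition rate, which only enters the fitting-duration accounting.
RECORD_WINDOW_S = 1.7e-3
DT_S = 1e-5
N1_LATENCY_S = 0.30e-3
P2_LATENCY_S = 0.60e-3
BUMP_SIGMA_S = 0.08e-3
ARTIFACT_TAU_S = 0.10e-3
P2_TO_N1_RATIO = 0.7
N_CURVES_PER_MEASUREMENT = 14  # seven anodic-leading + seven cathodic-leading
STIMULUS_RATE_HZ = 60.0

POLARITIES = ("anodic", "cathodic")


@dataclass
class EcapTrace:
    """One telemetry recording window.

    ``samples`` are in microvolts at the recording input; ``dt`` is seconds
    per sample.  ``n_curves`` records how many raw sweeps were averaged into
    this trace (1 for a single sweep, 14 for a standard measurement, in
    which case ``polarity`` is ``"averaged"``).
    """

    samples: np.ndarray
    dt: float
    stim_qu: float
    polarity: str
    channel: int
    n_curves: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite samples")
        if self.polarity not in POLARITIES + ("averaged",):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.samples.size) * self.dt

    @property
    def window_s(self) -> float:
        return self.samples.size * self.dt


@dataclass(frozen=True)
class PatientProfile:
    """Parameter bundle describing the population a patient is drawn from.

    Defaults describe an adult cohort with a fully functional array:

    * ECAP thresholds in [1, 4] qu with smooth across-array variation,
    * growth slopes in [20, 100] uV/qu,
    * recording noise 5 uV RMS,
    * a comfortable-loudness (MCL) profile that follows the threshold
      profile in attenuated form — clinical MCL profiles are flatter than
      ECAP threshold profiles, which is the premise of profile flattening —
      at an overall level of 12-25 qu with 5% independent per-channel
      variation.
    """

    thr_range: tuple[float, float] = (1.0, 4.0)
    slope_range: tuple[float, float] = (20.0, 100.0)
    noise_rms: float = 5.0
    artifact_scale: float = 200.0
    mcl_base_range: tuple[float, float] = (12.0, 25.0)
    mcl_profile_retain: float = 0.42
    mcl_jitter: float = 0.05
    p_unresponsive: float = 0.0
    disabled_channels: tuple[int, ...] = ()
    group: str = "adult"
    srt50_base_range: tuple[float, float] = (-4.0, 0.0)
    psychometric_slope: float = 0.15
    map_sensitivity: float = 10.0
    burst_sigma: float = 0.08
    fd_burst_median_min: float = 9.0  # 7.0 for children
    fd_burst_log_sd: float = 0.25

    def __post_init__(self) -> None:
        for name in ("thr_range", "slope_range", "mcl_base_range", "srt50_base_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if self.thr_range[0] <= 0 or self.slope_range[0] <= 0:
            raise ValueError("thresholds and slopes must be positive")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")
        if not 0.0 <= self.p_unresponsive <= 1.0:
            raise ValueError("p_unresponsive must be a probability")
        if self.group not in ("adult", "child"):
            raise ValueError("group must be 'adult' or 'child'")

    @classmethod
    def child(cls, **overrides) -> "PatientProfile":
        defaults = dict(group="child", fd_burst_median_min=7.0)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class VirtualPatient:
    """Ground truth for one simulated implant user."""

    layout: ElectrodeLayout
    true_ecap_thr: np.ndarray  # qu, per channel
    agf_slope: np.ndarray  # uV per qu, per channel
    noise_rms: float  # uV
    artifact_scale: float  # uV per qu
    true_mcl: np.ndarray  # qu, per channel
    listener: ListenerModel
    responsive: np.ndarray  # bool, per channel
    profile: PatientProfile = field(default_factory=PatientProfile)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.true_ecap_thr = np.asarray(self.true_ecap_thr, dtype=float)
        self.agf_slope = np.asarray(self.agf_slope, dtype=float)
        self.true_mcl = np.asarray(self.true_mcl, dtype=float)
        self.responsive = np.asarray(self.responsive, dtype=bool)
        for name in ("true_ecap_thr", "agf_slope", "true_mcl", "responsive"):
            if getattr(self, name).shape != (N_CHANNELS,):
                raise ValueError(f"{name} must have shape ({N_CHANNELS},)")
        if np.any(self.true_ecap_thr[self.responsive] <= 0):
            raise ValueError("responsive channels need positive ECAP thresholds")
        if np.any(self.agf_slope[self.responsive] <= 0):
            raise ValueError("responsive channels need positive growth slopes")
        if np.any(self.true_mcl[self.layout.active] <= 0):
            raise ValueError("active channels need positive true MCL")


def _smooth_channel_profile(rng: np.random.Generator, lo: float, hi: float,
                            n_control: int = 4, jitter_frac: float = 0.03) -> np.ndarray:
    """Draw a channel-correlated profile: linear interpolation between a few
    uniformly drawn control points, plus small independent jitter."""
    control_x = np.linspace(0, N_CHANNELS - 1, n_control)
    control_y = rng.uniform(lo, hi, n_control)
    prof = np.interp(np.arange(N_CHANNELS), control_x, control_y)
    prof += rng.normal(0.0, jitter_frac * (hi - lo), N_CHANNELS)
    return np.clip(prof, lo, hi)


def make_virtual_patient(seed: int, profile: PatientProfile | None = None) -> VirtualPatient:
    """Draw a virtual patient deterministically from a seed.

    ECAP thresholds vary smoothly along the array (few-control-point
    interpolation with small jitter); growth slopes are independent per
    channel.  The true comfortable-loudness profile is the threshold profile
    attenuated toward its mean (retaining ``mcl_profile_retain`` of the
    relative variation), scaled to an overall level drawn from
    ``mcl_base_range``, with independent per-channel jitter — emulating the
    clinical observation that MCL profiles are flatter than, but correlated
    with, ECAP threshold profiles.
    """
    profile = profile if profile is not None else PatientProfile()
    rng = np.random.default_rng(seed)

    thr = _smooth_channel_profile(rng, *profile.thr_range)
    slopes = rng.uniform(*profile.slope_range, N_CHANNELS)
    responsive = rng.random(N_CHANNELS) >= profile.p_unresponsive

    active = np.ones(N_CHANNELS, dtype=bool)
    active[list(profile.disabled_channels)] = False
    layout = ElectrodeLayout(active=active)

    m = thr.mean()
    shape = (m + profile.mcl_profile_retain * (thr - m)) / m
    level = rng.uniform(*profile.mcl_base_range)
    true_mcl = level * shape * (1.0 + rng.normal(0.0, profile.mcl_jitter, N_CHANNELS))
    true_mcl = np.maximum(true_mcl, 1e-3)

    listener = ListenerModel(
        srt50_base=float(rng.uniform(*profile.srt50_base_range)),
        slope=profile.psychometric_slope,
        map_sensitivity=profile.map_sensitivity,
    )
    return VirtualPatient(
        layout=layout,
        true_ecap_thr=thr,
        agf_slope=slopes,
        noise_rms=profile.noise_rms,
        artifact_scale=profile.artifact_scale,
        true_mcl=true_mcl,
        listener=listener,
        responsive=responsive,
        profile=profile,
        seed=seed,
    )


def _unit_bump(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def simulate_trace(
    patient: VirtualPatient,
    channel: int,
    stim_qu: float,
    polarity: str,
    rng: np.random.Generator,
) -> EcapTrace:
    """Simulate one raw telemetry sweep on a channel.

    samples = artifact + response + noise, where

    * artifact = s * artifact_scale * stim_qu * exp(-t / tau), with s = +1
      for anodic-leading and -1 for cathodic-leading pulses;
    * response = A * (-g(t; N1) + 0.7 * g(t; P2)) with unit-peak Gaussian
      bumps g and A = agf_slope * max(0, stim_qu - true_ecap_thr); A = 0 on
      non-responsive channels;
    * noise is i.i.d. Gaussian with sd ``noise_rms``.
    """
    if not 0 <= channel < N_CHANNELS:
        raise ValueError(f"unknown channel index {channel}")
    if polarity not in POLARITIES:
        raise ValueError(f"polarity must be one of {POLARITIES}")
    if stim_qu < 0:
        raise ValueError("stimulus charge must be non-negative")

    n = int(round(RECORD_WINDOW_S / DT_S))
    t = np.arange(n) * DT_S
    sign = 1.0 if polarity == "anodic" else -1.0
    artifact = sign * patient.artifact_scale * stim_qu * np.exp(-t / ARTIFACT_TAU_S)

    if patient.responsive[channel]:
        amp = patient.agf_slope[channel] * max(0.0, stim_qu - patient.true_ecap_thr[channel])
    else:
        amp = 0.0
    response = amp * (
        -_unit_bump(t, N1_LATENCY_S, BUMP_SIGMA_S)
        + P2_TO_N1_RATIO * _unit_bump(t, P2_LATENCY_S, BUMP_SIGMA_S)
    )
    noise = rng.normal(0.0, patient.noise_rms, n) if patient.noise_rms > 0 else 0.0
    return EcapTrace(
        samples=artifact + response + noise,
        dt=DT_S,
        stim_qu=float(stim_qu),
        polarity=polarity,
        channel=channel,
    )


def simulate_measurement(
    patient: VirtualPatient,
    channel: int,
    stim_qu: float,
    rng: np.random.Generator,
) -> EcapTrace:
    """One averaged measurement: the mean of 14 sweeps, 7 per leading polarity.

    The deterministic artifact term cancels exactly in the mean (equal counts
    of opposite signs); the effective noise sd drops to noise_rms/sqrt(14).
    """
    half = N_CURVES_PER_MEASUREMENT // 2
    traces = [
        simulate_trace(patient, channel, stim_qu, pol, rng)
        for pol in POLARITIES
        for _ in range(half)
    ]
    mean = np.mean([tr.samples for tr in traces], axis=0)
    return EcapTrace(
        samples=mean,
        dt=DT_S,
        stim_qu=float(stim_qu),
        polarity="averaged",
        channel=channel,
        n_curves=N_CURVES_PER_MEASUREMENT,
    )


def clin_map_of(patient: VirtualPatient) -> FittingMap:
    """The patient's everyday clinical map: MCL at the true comfortable
    profile, THR at 10% of MCL, default volume 90%."""
    mcl = np.where(patient.layout.active, patient.true_mcl, 0.0)
    clin = FittingMap(
        label="ClinMAP",
        mcl=mcl,
        thr=np.zeros(N_CHANNELS),
        active=patient.layout.active,
        volume=DEFAULT_VOLUME,
    )
    return set_thr_from_mcl(clin)


def patient_gain(patient: VirtualPatient, fitting_map: FittingMap) -> float:
    """Global loudness gain a patient would ask for on a given map.

    Feedback-driven live adjustment is modeled as scaling the map to the
    patient's comfortable level: the median over active channels of
    ``true_mcl / mcl``.  The median keeps the rule robust to single-channel
    profile mismatches.
    """
    act = fitting_map.active & patient.layout.active
    if not act.any():
        raise ValueError("no jointly active channels")
    mcl = fitting_map.mcl[act]
    if np.any(mcl <= 0):
        raise ValueError("map MCL must be positive on active channels")
    return float(np.median(patient.true_mcl[act] / mcl))


def burst_fit(
    patient: VirtualPatient,
    rng: np.random.Generator,
    sigma_b: float | None = None,
    balance_weight: float = 0.2,
    gain: float | None = None,
) -> tuple[FittingMap, float]:
    """Behavioral fitting with current bursts, then live loudness adjustment.

    Each active channel's burst MCL is the true comfortable level perturbed
    by multiplicative behavioral-judgement noise, ``true_mcl * (1 + eps)``
    with ``eps ~ N(0, sigma_b^2)`` (default from the patient profile,
    0.08).  Loudness balancing against the medial reference channel (E06, or
    the nearest active channel to it) then pulls each channel's *relative*
    loudness error toward the reference's:
    ``eps_i <- (1 - w) * eps_i + w * eps_ref``, so a noise-free fit
    reproduces the true profile exactly.  THR follows the 10% rule and the
    map is globally live-adjusted (median-ratio gain unless an explicit gain
    is given), yielding a LiveBurstMAP.

    Returns the map and the simulated fitting duration in minutes, drawn
    from a lognormal with median 9 min for adults and 7 min for children.
    """
    prof = patient.profile
    if sigma_b is None:
        sigma_b = prof.burst_sigma
    act = patient.layout.active

    eps = rng.normal(0.0, sigma_b, N_CHANNELS) if sigma_b > 0 else np.zeros(N_CHANNELS)
    active_idx = np.flatnonzero(act)
    ref = int(active_idx[np.argmin(np.abs(active_idx - 5))])  # E06 or nearest active
    eps = (1.0 - balance_weight) * eps + balance_weight * eps[ref]
    burst_mcl = np.where(act, patient.true_mcl * (1.0 + eps), 0.0)
    burst_mcl = np.maximum(burst_mcl, 0.0)

    burst = set_thr_from_mcl(
        FittingMap(
            label="BurstMAP",
            mcl=burst_mcl,
            thr=np.zeros(N_CHANNELS),
            active=act,
            volume=DEFAULT_VOLUME,
        )
    )
    g = patient_gain(patient, burst) if gain is None else float(gain)
    live = global_adjust(burst, g)

    fd_minutes = float(
        prof.fd_burst_median_min * np.exp(rng.normal(0.0, prof.fd_burst_log_sd))
    )
    return live, fd_minutes


# ---------------------------------------------------------------------------
# Patient serialization (JSON), used by the command-line interface.

def patient_to_dict(patient: VirtualPatient) -> dict:
    return {
        "seed": patient.seed,
        "group": patient.profile.group,
        "noise_rms_uv": patient.noise_rms,
        "artifact_scale_uv_per_qu": patient.artifact_scale,
        "listener": {
            "srt50_base_db": patient.listener.srt50_base,
            "slope_per_db": patient.listener.slope,
            "map_sensitivity_db": patient.listener.map_sensitivity,
        },
        "channels": [
            {
                "id": channel_label(i),
                "active": bool(patient.layout.active[i]),
                "responsive": bool(patient.responsive[i]),
                "ecap_threshold_qu": float(patient.true_ecap_thr[i]),
                "agf_slope_uv_per_qu": float(patient.agf_slope[i]),
                "true_mcl_qu": float(patient.true_mcl[i]),
            }
            for i in range(N_CHANNELS)
        ],
    }


def patient_from_dict(data: dict) -> VirtualPatient:
    channels = data["channels"]
    if len(channels) != N_CHANNELS:
        raise ValueError(f"expected {N_CHANNELS} channels, got {len(channels)}")
    active = np.array([c["active"] for c in channels], dtype=bool)
    listener = data["listener"]
    group = data.get("group", "adult")
    profile = PatientProfile() if group == "adult" else PatientProfile.child()
    return VirtualPatient(
        layout=ElectrodeLayout(active=active),
        true_ecap_thr=np.array([c["ecap_threshold_qu"] for c in channels]),
        agf_slope=np.array([c["agf_slope_uv_per_qu"] for c in channels]),
        noise_rms=float(data["noise_rms_uv"]),
        artifact_scale=float(data["artifact_scale_uv_per_qu"]),
        true_mcl=np.array([c["true_mcl_qu"] for c in channels]),
        listener=ListenerModel(
            srt50_base=float(listener["srt50_base_db"]),
            slope=float(listener["slope_per_db"]),
            map_sensitivity=float(listener["map_sensitivity_db"]),
        ),
        responsive=np.array([c["responsive"] for c in channels], dtype=bool),
        profile=profile,
        seed=data.get("seed"),
    )


def write_patient(path: str | Path, patient: VirtualPatient) -> None:
    Path(path).write_text(json.dumps(patient_to_dict(patient), indent=2) + "\n")


def read_patient(path: str | Path) -> VirtualPatient:
    return patient_from_dict(json.loads(Path(path).read_text()))
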