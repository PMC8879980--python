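"""ECAP-based initial map builder: quick-mode scheduling, threshold profile
completion, flattening, scaling, fallback, and live adjustment.

The builder turns automatically measured ECAP thresholds into an initial
fitting map in five steps:

1. *Quick-mode scheduling*: thresholds are measured on at least four
   channels, alternating between the basal, medial, and apical sections of
   the array so the measured channels span the whole electrode.
2. *Profile completion*: on channels without a measured threshold, linear
   inter- and extrapolation over the channel index fills the gaps.
3. *Flattening*: the completed threshold profile is compressed toward its
   across-channel mean so that only 42% of the original profile's variation
   remains — clinical MCL profiles are flatter than ECAP threshold profiles.
4. *Scaling*: the flattened profile is scaled so the maximum MCL in the
   initial map is exactly 5 qu, preserving the profile shape.  The low
   ceiling guarantees the initial map is not uncomfortably loud before live
   adjustment.
5. *Live adjustment*: the audiologist switches the map to live mode and
   scales all channels globally to the listener's comfortable loudness.

If too few thresholds are found, or the found channels are not spatially
well distributed, the builder falls back to a flat map with all active MCLs
at the 5 qu maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agf import AgfConfig, EcapThresholdResult, estimate_threshold, measure_agf
from .ecap_sim import (
    N_CURVES_PER_MEASUREMENT,
    STIMULUS_RATE_HZ,
    VirtualPatient,
    patient_gain,
)
from .maps import (
    DEFAULT_VOLUME,
    N_CHANNELS,
    ElectrodeLayout,
    FittingMap,
    channel_label,
    check_eligibility,
    global_adjust,
    section_of,
    set_thr_from_mcl,
)

#: Default quick-mode measurement order (0-based indices): cycles
#: basal -> medial -> apical, starting mid-section and spreading outward, so
#: the first four channels (E10, E06, E03, E12) already span all sections.
DEFAULT_QUICKMODE_ORDER = (9, 5, 2, 11, 6, 1, 8, 4, 0, 10, 7, 3)

RETAIN_FRACTION = 0.42
TARGET_MAX_QU = 5.0
MIN_THRESHOLD_QU = 0.1
MIN_FOUND = 3
TARGET_FOUND = 4
MIN_SPAN = 5  # found channels must span > MIN_SPAN index positions

PROVENANCE_TAGS = ("measured", "interpolated", "extrapolated", "absent")


class EligibilityError(ValueError):
    """Raised when an array has too few active channels for ECAP fitting."""


@dataclass(frozen=True)
class ArtfitConfig:
    """Tunables of the map builder.

    The fitting-duration model charges 14 curves at the 60 Hz stimulus
    repetition rate per averaged measurement (~0.23 s), a fixed per-channel
    setup overhead, and a fixed live-adjustment overhead.
    """

    agf: AgfConfig = field(default_factory=AgfConfig)
    retain: float = RETAIN_FRACTION
    target_max_qu: float = TARGET_MAX_QU
    min_found: int = MIN_FOUND
    target_found: int = TARGET_FOUND
    per_channel_overhead_s: float = 20.0
    live_adjust_s: float = 60.0
    volume: float = DEFAULT_VOLUME

    @property
    def per_measurement_s(self) -> float:
        return N_CURVES_PER_MEASUREMENT / STIMULUS_RATE_HZ


@dataclass
class ThresholdProfile:
    """Per-channel threshold estimates with provenance bookkeeping."""

    threshold_qu: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        self.threshold_qu = np.asarray(self.threshold_qu, dtype=float)
        if self.threshold_qu.shape != (N_CHANNELS,):
            raise ValueError(f"threshold_qu must have shape ({N_CHANNELS},)")
        if len(self.provenance) != N_CHANNELS:
            raise ValueError("provenance must cover all channels")
        for tag in self.provenance:
            if tag not in PROVENANCE_TAGS:
                raise ValueError(f"unknown provenance tag {tag!r}")


@dataclass
class ArtfitDiagnostics:
    """What the builder did: schedule, found counts, fallback, duration."""

    measured_channels: list[int]
    n_found: int
    well_distributed: bool
    fallback_used: bool
    fd_minutes: float

    @property
    def measured_labels(self) -> list[str]:
        return [channel_label(i) for i in self.measured_channels]


def quickmode_schedule(layout: ElectrodeLayout) -> list[int]:
    """Deterministic measurement order alternating across array sections.

    Walks the default order (E10, E06, E03, E12, E07, E02, ...) over active
    channels.  A disabled channel is substituted by the nearest not-yet
    scheduled active channel within the same section, preferring the basal
    side on distance ties; if the section has no free active channel, the
    slot is skipped.  Raises :class:`EligibilityError` with fewer than four
    active channels.
    """
    if layout.n_active < 4:
        raise EligibilityError(
            f"quick mode needs at least 4 active channels, got {layout.n_active}"
        )
    schedule: list[int] = []
    for ch in DEFAULT_QUICKMODE_ORDER:
        if layout.active[ch]:
            if ch not in schedule:
                schedule.append(ch)
            continue
        candidates = [
            c for c in layout.active_in_section(section_of(ch)) if c not in schedule
        ]
        if candidates:
            # distance first; on ties prefer the basal (higher-index) side,
            # then the lower index.
            best = min(candidates, key=lambda c: (abs(c - ch), c < ch, c))
            schedule.append(best)
    return schedule


def complete_profile(
    found: list[EcapThresholdResult], layout: ElectrodeLayout
) -> ThresholdProfile:
    """Fill unmeasured channels by linear inter-/extrapolation over index.

    Between two found channels the threshold is linear in the channel index;
    beyond the outermost found channels the line through the two nearest
    found thresholds is continued (a single found threshold gives a constant
    profile).  Results are clipped at 0.1 qu from below.  Inactive channels
    are tagged ``absent`` and carry 0.
    """
    results = [r for r in found if r.found]
    if not results:
        raise ValueError("no found thresholds: fallback map required")
    by_channel = {r.channel: float(r.threshold_qu) for r in results}
    idx = np.array(sorted(by_channel), dtype=float)
    vals = np.array([by_channel[int(i)] for i in idx])

    thresholds = np.zeros(N_CHANNELS)
    provenance = ["absent"] * N_CHANNELS
    for ch in range(N_CHANNELS):
        if not layout.active[ch]:
            continue
        if ch in by_channel:
            thresholds[ch] = by_channel[ch]
            provenance[ch] = "measured"
        elif idx[0] <= ch <= idx[-1]:
            thresholds[ch] = np.interp(ch, idx, vals)
            provenance[ch] = "interpolated"
        else:
            if idx.size == 1:
                thresholds[ch] = vals[0]
            elif ch < idx[0]:
                slope = (vals[1] - vals[0]) / (idx[1] - idx[0])
                thresholds[ch] = vals[0] + slope * (ch - idx[0])
            else:
                slope = (vals[-1] - vals[-2]) / (idx[-1] - idx[-2])
                thresholds[ch] = vals[-1] + slope * (ch - idx[-1])
            provenance[ch] = "extrapolated"
        thresholds[ch] = max(thresholds[ch], MIN_THRESHOLD_QU)
    return ThresholdProfile(threshold_qu=thresholds, provenance=provenance)


def flatten_profile(
    values: np.ndarray | ThresholdProfile,
    retain: float = RETAIN_FRACTION,
    active: np.ndarray | None = None,
) -> np.ndarray:
    """Compress a threshold profile toward its mean, retaining a fraction
    of the original variation.

    ``f_i = m + retain * (t_i - m)`` with ``m`` the mean over active
    channels.  The mean is preserved exactly and the peak-to-peak of the
    output equals ``retain`` times the peak-to-peak of the input.  With the
    default ``retain = 0.42``, only 42% of the original threshold profile's
    variation remains in the flattened profile.
    """
    if not 0.0 < retain <= 1.0:
        raise ValueError(f"retain must be in (0, 1], got {retain}")
    if isinstance(values, ThresholdProfile):
        values = values.threshold_qu
    values = np.asarray(values, dtype=float)
    if active is None:
        active = np.ones(values.shape, dtype=bool)
    active = np.asarray(active, dtype=bool)
    m = values[active].mean()
    out = np.where(active, m + retain * (values - m), 0.0)
    return out


def scale_to_max(
    values: np.ndarray,
    target_max: float = TARGET_MAX_QU,
    active: np.ndarray | None = None,
) -> np.ndarray:
    """Scale a profile so its maximum over active channels equals
    ``target_max`` (5 qu by default), preserving channel ratios."""
    values = np.asarray(values, dtype=float)
    if active is None:
        active = np.ones(values.shape, dtype=bool)
    active = np.asarray(active, dtype=bool)
    peak = values[active].max()
    if peak <= 0:
        raise ValueError("profile maximum must be positive")
    return np.where(active, values * (target_max / peak), 0.0)


def _well_distributed(found_channels: list[int]) -> bool:
    """Spatial-distribution gate for the fallback decision: the found
    channels must cover at least two of the three array sections and span
    more than :data:`MIN_SPAN` index positions."""
    if not found_channels:
        return False
    sections = {section_of(c) for c in found_channels}
    span = max(found_channels) - min(found_channels)
    return len(sections) >= 2 and span >= MIN_SPAN


def build_ecap_map(
    patient: VirtualPatient,
    config: ArtfitConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FittingMap, ArtfitDiagnostics]:
    """Run the full quick-mode measurement and map construction.

    Measures AGFs and estimates thresholds channel by channel along the
    quick-mode schedule until four thresholds are found or the schedule is
    exhausted.  With at least three well-distributed found thresholds the
    profile is completed, flattened, and scaled to a 5 qu maximum;
    otherwise a flat map at 5 qu on all active channels is produced
    (``fallback_used`` in the diagnostics).  THR is set to 10% of MCL,
    the volume to 90%, and channels disabled in the patient's layout (those
    disabled in the clinical map) stay disabled.
    """
    config = config if config is not None else ArtfitConfig()
    rng = rng if rng is not None else np.random.default_rng()
    report = check_eligibility(patient.layout)
    if not report.eligible:
        raise EligibilityError(
            f"only {report.n_active} active channels; ECAP fitting needs >= 10"
        )

    schedule = quickmode_schedule(patient.layout)
    results: list[EcapThresholdResult] = []
    measured: list[int] = []
    for ch in schedule:
        agf = measure_agf(patient, ch, config=config.agf, rng=rng)
        results.append(estimate_threshold(agf))
        measured.append(ch)
        if sum(r.found for r in results) >= config.target_found:
            break

    found = [r for r in results if r.found]
    found_channels = [r.channel for r in found]
    n_found = len(found)
    well = _well_distributed(found_channels)
    fallback = n_found < config.min_found or not well

    active = patient.layout.active
    if fallback:
        mcl = np.where(active, config.target_max_qu, 0.0)
    else:
        profile = complete_profile(found, patient.layout)
        flattened = flatten_profile(profile, retain=config.retain, active=active)
        mcl = scale_to_max(flattened, target_max=config.target_max_qu, active=active)

    ecap_map = set_thr_from_mcl(
        FittingMap(
            label="ECAPMAP",
            mcl=mcl,
            thr=np.zeros(N_CHANNELS),
            active=active,
            volume=config.volume,
        )
    )
    n_levels = config.agf.levels.size
    fd_s = len(measured) * (n_levels * config.per_measurement_s + config.per_channel_overhead_s)
    diagnostics = ArtfitDiagnostics(
        measured_channels=measured,
        n_found=n_found,
        well_distributed=well,
        fallback_used=fallback,
        fd_minutes=fd_s / 60.0,
    )
    return ecap_map, diagnostics


def live_adjust_ecap(
    ecap_map: FittingMap,
    patient: VirtualPatient,
    fd_minutes: float = 0.0,
    config: ArtfitConfig | None = None,
) -> tuple[FittingMap, float]:
    """Globally adjust an initial ECAP map to comfortable loudness.

    Applies the patient's feedback-driven gain (median ratio of the true
    comfortable profile to the map's MCLs), re-applies the 10% THR rule, and
    adds the live-adjustment time to the running fitting duration.  Returns
    the LiveECAPMAP and the accumulated fitting duration in minutes.
    """
    config = config if config is not None else ArtfitConfig()
    gain = patient_gain(patient, ecap_map)
    live = global_adjust(ecap_map, gain)
    return live, fd_minutes + config.live_adjust_s / 60.0
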