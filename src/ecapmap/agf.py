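"""Measurement chain: preprocessing, N1-P2 amplitude, AGF acquisition,
and automatic ECAP threshold estimation.

The amplitude growth function (AGF) relates ECAP response amplitude to
stimulus charge.  Sampling it in small charge steps and extrapolating the
supra-threshold linear segment down to zero amplitude yields the ECAP
threshold — the automatic threshold determination this package implements.

Preprocessing follows the recording chain of the clinical system: the first
part of the window is blanked (zeroed) to suppress amplifier saturation by
the stimulation artifact, the signal is amplified 100x and low-pass filtered
at 5 kHz (4th-order, applied forward-backward for zero phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .ecap_sim import DT_S, EcapTrace, VirtualPatient, simulate_measurement

AMPLIFIER_GAIN = 100.0
LOWPASS_HZ = 5000.0
LOWPASS_ORDER = 4
BLANKING_S = 0.15e-3
#: Search windows for the N1 trough and P2 peak, in seconds.
N1_WINDOW_S = (0.20e-3, 0.45e-3)
P2_WINDOW_S = (0.45e-3, 0.90e-3)

#: Supra-noise criterion and fit-quality gate for a "threshold found" call.
SNR_CRITERION = 3.0
MIN_R2_FOR_FOUND = 0.8
MIN_SUPRA_POINTS = 4
MIN_AGF_POINTS = 6
N_BASELINE_LEVELS = 5


@dataclass(frozen=True)
class AgfConfig:
    """Stimulus sweep settings for AGF acquisition.

    Defaults sweep 0.5 to 6 qu in 0.1 qu steps with 14 averaged curves per
    level, i.e., a fine-grained sampling of the growth function.
    """

    start_qu: float = 0.5
    step_qu: float = 0.1
    max_qu: float = 6.0
    n_curves: int = 14

    def __post_init__(self) -> None:
        if self.max_qu <= self.start_qu:
            raise ValueError("max_qu must exceed start_qu")
        if self.step_qu <= 0:
            raise ValueError("step_qu must be positive")

    @property
    def levels(self) -> np.ndarray:
        n = int(np.floor((self.max_qu - self.start_qu) / self.step_qu)) + 1
        return self.start_qu + self.step_qu * np.arange(n)


@dataclass
class AGF:
    """An acquired amplitude growth function for one channel.

    Points are (stimulus charge in qu, response amplitude in uV), sorted
    ascending in charge with no duplicates.  ``noise_floor_uv`` is a robust
    estimate of the amplitude-metric noise taken from the sub-threshold
    baseline levels.
    """

    channel: int
    stim_qu: np.ndarray
    amplitude_uv: np.ndarray
    noise_floor_uv: float

    def __post_init__(self) -> None:
        self.stim_qu = np.asarray(self.stim_qu, dtype=float)
        self.amplitude_uv = np.asarray(self.amplitude_uv, dtype=float)
        if self.stim_qu.shape != self.amplitude_uv.shape:
            raise ValueError("stim_qu and amplitude_uv must have equal length")
        if np.any(np.diff(self.stim_qu) <= 0):
            raise ValueError("stim_qu must be strictly increasing")
        if np.any(self.amplitude_uv < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.stim_qu.tolist(), self.amplitude_uv.tolist()))

    @property
    def n_points(self) -> int:
        return self.stim_qu.size


@dataclass
class EcapThresholdResult:
    """Outcome of automatic threshold estimation on one channel."""

    channel: int
    threshold_qu: float | None
    found: bool
    fit_slope: float  # uV per qu, of the amplitude metric
    fit_r2: float
    n_supra: int

    def __post_init__(self) -> None:
        if self.found and (self.threshold_qu is None or self.threshold_qu <= 0):
            raise ValueError("a found threshold must be positive")
        if not self.found and self.threshold_qu is not None:
            raise ValueError("threshold_qu must be absent when not found")


def preprocess_trace(trace: EcapTrace) -> EcapTrace:
    """Blank the stimulus interval, amplify 100x, and low-pass at 5 kHz.

    The first 0.15 ms of the window is zeroed (blanking), the remainder is
    multiplied by the system gain of 100 and filtered with a 4th-order
    low-pass at 5 kHz applied forward-backward (zero phase).
    """
    if trace.window_s <= BLANKING_S:
        raise ValueError("recording window shorter than the blanking interval")
    samples = trace.samples.copy()
    samples[trace.t < BLANKING_S] = 0.0
    samples *= AMPLIFIER_GAIN
    sos = butter(LOWPASS_ORDER, LOWPASS_HZ, btype="low", fs=1.0 / trace.dt, output="sos")
    samples = sosfiltfilt(sos, samples)
    return EcapTrace(
        samples=samples,
        dt=trace.dt,
        stim_qu=trace.stim_qu,
        polarity=trace.polarity,
        channel=trace.channel,
        n_curves=trace.n_curves,
    )


def ecap_amplitude(trace: EcapTrace) -> float:
    """N1-P2 peak-to-peak amplitude of a preprocessed trace, in uV at input.

    The amplitude is the maximum over the P2 window minus the minimum over
    the N1 window, floored at zero, divided by the amplifier gain so the
    value is reported at the recording-input scale.
    """
    t = trace.t
    n_win = trace.samples[(t >= N1_WINDOW_S[0]) & (t < N1_WINDOW_S[1])]
    p_win = trace.samples[(t >= P2_WINDOW_S[0]) & (t < P2_WINDOW_S[1])]
    if n_win.size == 0 or p_win.size == 0:
        raise ValueError("trace does not cover the N1/P2 search windows")
    return max(0.0, float(p_win.max() - n_win.min())) / AMPLIFIER_GAIN


def measure_agf(
    patient: VirtualPatient,
    channel: int,
    config: AgfConfig | None = None,
    rng: np.random.Generator | None = None,
) -> AGF:
    """Sweep the stimulus from start to max level and record the AGF.

    One averaged measurement (14 curves) is taken per level; each trace is
    preprocessed and reduced to its N1-P2 amplitude.  The noise floor is the
    robust standard deviation (1.4826 * MAD) of the amplitudes at the lowest
    five levels, which lie on the sub-threshold plateau for the default
    population (thresholds >= 1 qu, sweep start 0.5 qu).
    """
    config = config if config is not None else AgfConfig()
    rng = rng if rng is not None else np.random.default_rng()
    levels = config.levels
    amplitudes = np.empty(levels.size)
    for k, level in enumerate(levels):
        meas = simulate_measurement(patient, channel, float(level), rng)
        amplitudes[k] = ecap_amplitude(preprocess_trace(meas))
    amplitudes[amplitudes < 1e-12] = 0.0  # snap filter round-off to zero
    baseline = amplitudes[:N_BASELINE_LEVELS]
    noise_floor = 1.4826 * float(np.median(np.abs(baseline - np.median(baseline))))
    if noise_floor < 1e-12:
        noise_floor = 0.0
    return AGF(
        channel=channel,
        stim_qu=levels,
        amplitude_uv=amplitudes,
        noise_floor_uv=noise_floor,
    )


def _supra_noise_run(agf: AGF) -> np.ndarray:
    """Boolean mask of the contiguous run of supra-noise points that ends at
    the highest stimulated level.

    A point is supra-noise when its amplitude exceeds the baseline amplitude
    level (the median over the lowest sweep levels — the N1-P2 metric of
    pure noise has a positive mean) by more than three times the noise
    floor.  For noise-free data both terms are zero and any positive
    amplitude qualifies.  Restricting the fit to the top contiguous run
    keeps isolated baseline noise excursions out of the regression, which
    would otherwise drag the x-intercept toward zero.
    """
    baseline_offset = float(np.median(agf.amplitude_uv[:N_BASELINE_LEVELS]))
    supra = agf.amplitude_uv > baseline_offset + SNR_CRITERION * agf.noise_floor_uv
    mask = np.zeros_like(supra)
    for i in range(supra.size - 1, -1, -1):
        if supra[i]:
            mask[i] = True
        else:
            break
    return mask


def estimate_threshold(agf: AGF) -> EcapThresholdResult:
    """Estimate the ECAP threshold as the x-intercept of the linear AGF.

    A least-squares line is fitted through the supra-noise points (the
    contiguous run below the maximum level), after subtracting the baseline
    amplitude offset (the noise metric's positive mean, estimated as the
    median amplitude over the lowest sweep levels) so the extrapolation
    target is the true zero of the neural response; the threshold is where
    the line crosses zero.  The threshold counts as *found* only when the
    fitted slope is positive, the fit explains the data well (R^2 >= 0.8),
    and the intercept lies within (0, max stimulated level].  Otherwise the
    result reports ``found = False`` with no threshold — the map builder
    then falls back to inter-/extrapolation or a flat map.
    """
    if agf.n_points < MIN_AGF_POINTS:
        raise ValueError(f"need at least {MIN_AGF_POINTS} AGF points")
    mask = _supra_noise_run(agf)
    n_supra = int(mask.sum())

    slope = float("nan")
    r2 = 0.0
    threshold = None
    found = False
    if n_supra >= MIN_SUPRA_POINTS:
        baseline_offset = float(np.median(agf.amplitude_uv[:N_BASELINE_LEVELS]))
        x = agf.stim_qu[mask]
        y = agf.amplitude_uv[mask] - baseline_offset
        slope, intercept = np.polyfit(x, y, 1)
        slope = float(slope)
        pred = slope * x + intercept
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        if slope > 0:
            x_intercept = -float(intercept) / slope
            if r2 >= MIN_R2_FOR_FOUND and 0.0 < x_intercept <= float(agf.stim_qu.max()):
                threshold = x_intercept
                found = True
    return EcapThresholdResult(
        channel=agf.channel,
        threshold_qu=threshold,
        found=found,
        fit_slope=slope,
        fit_r2=float(r2),
        n_supra=n_supra,
    )
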