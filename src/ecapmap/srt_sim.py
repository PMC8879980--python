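"""Adaptive speech-reception-threshold (SRT50) test simulator.

Models an adaptive sentence-in-noise test of the matrix type: speech is
presented at a fixed level (65 dB SPL) while the noise level is adapted from
sentence to sentence until the signal-to-noise ratio at which the listener
repeats 50% of the words correctly (the SRT50) is bracketed.

The listener is a psychometric model: the probability of repeating a word
correctly is a logistic function of the SNR, centered on the listener's
*effective* SRT50.  The effective SRT50 couples speech performance to map
quality: deviations of the map's MCL profile from the listener's everyday
clinical map raise the SRT (i.e., worsen performance) in proportion to the
root-mean-square relative MCL deviation.  Setting ``map_sensitivity = 0``
recovers a map-independent listener, which is useful for null testing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .maps import FittingMap

SPEECH_LEVEL_DB_SPL = 65.0
TRAINING_START_SNR_DB = 20.0
TEST_START_OFFSET_DB = 10.0
DEFAULT_N_SENTENCES = 14
DEFAULT_WORDS_PER_SENTENCE = 5
#: Adaptive step schedule: the step shrinks geometrically from the initial
#: to the final value, halving at each direction reversal of the track.
DEFAULT_STEP_INIT_DB = 4.0
DEFAULT_STEP_FINAL_DB = 1.0
DEFAULT_STEP_DECAY = 0.5
#: The SRT estimate is the mean presented SNR over this many final sentences.
N_ESTIMATE_SENTENCES = 8


@dataclass(frozen=True)
class ListenerModel:
    """Psychometric description of a virtual listener.

    Parameters
    ----------
    srt50_base : float
        Intrinsic SRT50 in dB SNR, i.e., the SRT the listener would reach
        with a perfectly fitted map.
    slope : float
        Slope of the psychometric function at the 50% point, in probability
        per dB.  Must be positive.
    map_sensitivity : float
        dB of SRT penalty per unit RMS relative MCL deviation of the tested
        map from the clinical map.  Non-negative.
    """

    srt50_base: float
    slope: float = 0.15
    map_sensitivity: float = 10.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("psychometric slope must be positive")
        if self.map_sensitivity < 0:
            raise ValueError("map_sensitivity must be non-negative")


@dataclass
class SrtRunResult:
    """Result of one adaptive list: the SRT estimate and the SNR track."""

    srt_estimate: float
    n_sentences: int
    track: np.ndarray

    def __post_init__(self) -> None:
        self.track = np.asarray(self.track, dtype=float)
        if self.track.shape != (self.n_sentences,):
            raise ValueError("track length must equal n_sentences")


def effective_srt(listener: ListenerModel, fitting_map: FittingMap,
                  clin: FittingMap) -> float:
    """Effective SRT50 of a listener tested with a given map.

    The penalty term is ``map_sensitivity`` times the RMS over jointly active
    channels of the relative MCL deviation ``(MCL_map - MCL_clin)/MCL_clin``.
    With ``fitting_map == clin`` the effective SRT equals ``srt50_base``.
    """
    both = fitting_map.active & clin.active
    if not both.any():
        raise ValueError("maps share no active channels")
    ref = clin.mcl[both]
    if np.any(ref <= 0):
        raise ValueError("clinical MCL must be positive on active channels")
    rel = (fitting_map.mcl[both] - ref) / ref
    rms = float(np.sqrt(np.mean(rel**2)))
    return listener.srt50_base + listener.map_sensitivity * rms


def word_correct_prob(listener_srt: float, snr: float, slope: float = 0.15) -> float:
    """Logistic word-correct probability at a given SNR.

    Normalized so that the derivative at the 50% point equals ``slope``
    (probability per dB): ``p = 1 / (1 + exp(-4 * slope * (snr - srt)))``.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    x = 4.0 * slope * (snr - listener_srt)
    if x < -700.0:  # avoid math.exp overflow for extreme slopes
        return 0.0
    return 1.0 / (1.0 + math.exp(-x))


def run_adaptive_list(
    listener_srt: float,
    start_snr: float,
    rng: np.random.Generator,
    slope: float = 0.15,
    n_sentences: int = DEFAULT_N_SENTENCES,
    words_per_sentence: int = DEFAULT_WORDS_PER_SENTENCE,
    step_init: float = DEFAULT_STEP_INIT_DB,
    step_final: float = DEFAULT_STEP_FINAL_DB,
    step_decay: float = DEFAULT_STEP_DECAY,
) -> SrtRunResult:
    """Run one adaptive sentence list and estimate the SRT50.

    Each sentence presents ``words_per_sentence`` words scored as independent
    Bernoulli trials with the listener's word-correct probability at the
    current SNR.  The SNR update after sentence ``k`` is::

        snr[k+1] = snr[k] - step * (prop_correct - 0.5) / 0.5

    The step starts at ``step_init`` and shrinks geometrically (by
    ``step_decay``) each time the track reverses direction, floored at
    ``step_final`` — large steps cover the initial distance to the
    threshold quickly, small steps then resolve it.  The SRT estimate is the
    mean presented SNR over the final :data:`N_ESTIMATE_SENTENCES`
    sentences.  Speech stays fixed at 65 dB SPL; the noise level is
    ``speech - snr``.
    """
    if n_sentences < 10:
        raise ValueError("an adaptive list needs at least 10 sentences")
    if slope <= 0:
        raise ValueError("slope must be positive")
    snr = float(start_snr)
    track = np.empty(n_sentences)
    step = step_init
    prev_direction = 0.0
    for k in range(n_sentences):
        track[k] = snr
        p = word_correct_prob(listener_srt, snr, slope=slope)
        n_correct = rng.binomial(words_per_sentence, p)
        prop = n_correct / words_per_sentence
        delta = -step * (prop - 0.5) / 0.5
        direction = float(np.sign(delta))
        if prev_direction != 0.0 and direction != 0.0 and direction != prev_direction:
            step = max(step_final, step * step_decay)
        if direction != 0.0:
            prev_direction = direction
        snr += delta
    estimate = float(np.mean(track[-N_ESTIMATE_SENTENCES:]))
    return SrtRunResult(srt_estimate=estimate, n_sentences=n_sentences, track=track)


def training_then_tests(
    listener: ListenerModel,
    clin: FittingMap,
    burst_live: FittingMap,
    ecap_live: FittingMap,
    rng: np.random.Generator,
    group: str = "adult",
) -> dict[str, float]:
    """Full test-session protocol: training with the clinical map, then tests.

    Training lists (two for adults, one for children) are run with the
    clinical map starting at +20 dB SNR.  The test lists start at the
    (average) training SRT plus 10 dB, which creates comparable initial
    conditions across maps.  The order of the three test maps is
    pseudo-randomized from the supplied generator; adults run two test lists
    per map and the per-map SRT is their mean, children run one.

    Returns a dict mapping map label to the measured SRT in dB SNR.
    """
    if group not in ("adult", "child"):
        raise ValueError("group must be 'adult' or 'child'")
    n_lists = 2 if group == "adult" else 1

    srt_train = effective_srt(listener, clin, clin)
    training = [
        run_adaptive_list(srt_train, TRAINING_START_SNR_DB, rng, slope=listener.slope)
        for _ in range(n_lists)
    ]
    start = float(np.mean([r.srt_estimate for r in training])) + TEST_START_OFFSET_DB

    maps = [clin, burst_live, ecap_live]
    order = rng.permutation(len(maps))
    results: dict[str, float] = {}
    for idx in order:
        m = maps[idx]
        srt_true = effective_srt(listener, m, clin)
        runs = [
            run_adaptive_list(srt_true, start, rng, slope=listener.slope)
            for _ in range(n_lists)
        ]
        results[m.label] = float(np.mean([r.srt_estimate for r in runs]))
    return results
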