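"""Fitting-map data model, validation, and JSON serialization.

A *fitting map* is the per-channel parameter set programmed into a cochlear
implant audio processor: for each of the 12 channels of a MED-EL style
electrode array it holds the maximum comfortable loudness level (MCL) and
the behavioral threshold level (THR), both expressed as charge in the
manufacturer's charge units (qu), plus an active flag per channel and a
global volume setting in percent.

Conventions used throughout this package:

* Channels are stored apical-to-basal; index 0 is the most apical channel
  and carries the label ``E01``, index 11 is the most basal (``E12``).
* The array is partitioned into three equal sections: apical ``E01-E04``,
  medial ``E05-E08``, basal ``E09-E12``.
* Disabled channels carry ``mcl = thr = 0`` rather than being removed, so
  per-channel statistics stay aligned across maps.
* On active channels of any map produced by this toolkit, the THR is fixed
  at 10% of the MCL (the recommended default of the clinical fitting
  software), and the default volume is 90%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

N_CHANNELS = 12
THR_FRACTION = 0.10
DEFAULT_VOLUME = 90.0
MIN_ACTIVE_FOR_ELIGIBILITY = 10

#: Recognized map kinds.  The "Live" variants are the result of the global
#: loudness adjustment applied with the map running in live mode.
MAP_LABELS = (
    "ClinMAP",
    "BurstMAP",
    "LiveBurstMAP",
    "ECAPMAP",
    "LiveECAPMAP",
    "FlatMAP",
)

#: Label promotion applied by :func:`global_adjust`.
_LIVE_PROMOTION = {"BurstMAP": "LiveBurstMAP", "ECAPMAP": "LiveECAPMAP"}

SECTION_NAMES = ("apical", "medial", "basal")
#: Channel indices (0-based) belonging to each section.
SECTIONS = {
    "apical": tuple(range(0, 4)),
    "medial": tuple(range(4, 8)),
    "basal": tuple(range(8, 12)),
}


def channel_label(index: int) -> str:
    """Return the 1-based channel label (``E01`` ... ``E12``) for an index."""
    if not 0 <= index < N_CHANNELS:
        raise ValueError(f"channel index out of range: {index}")
    return f"E{index + 1:02d}"


def channel_index(label: str) -> int:
    """Parse a channel label such as ``E06`` into a 0-based index."""
    try:
        idx = int(str(label).lstrip("Ee")) - 1
    except ValueError as exc:
        raise ValueError(f"malformed channel label: {label!r}") from exc
    if not 0 <= idx < N_CHANNELS:
        raise ValueError(f"channel label out of range: {label!r}")
    return idx


def section_of(index: int) -> str:
    """Name of the array section (apical/medial/basal) a channel belongs to."""
    for name, members in SECTIONS.items():
        if index in members:
            return name
    raise ValueError(f"channel index out of range: {index}")


@dataclass(frozen=True)
class ElectrodeLayout:
    """A 12-channel electrode array with per-channel active flags.

    The sections partition is fixed (apical E01-E04, medial E05-E08, basal
    E09-E12); only the active flags vary between individuals, typically
    because impedance telemetry identified defective electrodes.
    """

    active: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.active, dtype=bool)
        if arr.shape != (N_CHANNELS,):
            raise ValueError(
                f"layout must have exactly {N_CHANNELS} channels, got shape {arr.shape}"
            )
        object.__setattr__(self, "active", arr)

    @property
    def n_channels(self) -> int:
        return N_CHANNELS

    @property
    def sections(self) -> dict[str, tuple[int, ...]]:
        return dict(SECTIONS)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def active_in_section(self, name: str) -> list[int]:
        return [i for i in SECTIONS[name] if self.active[i]]

    @classmethod
    def fully_active(cls) -> "ElectrodeLayout":
        return cls(active=np.ones(N_CHANNELS, dtype=bool))

    @classmethod
    def with_disabled(cls, disabled: list[int] | tuple[int, ...]) -> "ElectrodeLayout":
        act = np.ones(N_CHANNELS, dtype=bool)
        act[list(disabled)] = False
        return cls(active=act)


@dataclass(frozen=True)
class EligibilityReport:
    """Outcome of the >= 10 active channels participation rule."""

    n_active: int
    eligible: bool


@dataclass
class FittingMap:
    """Per-channel MCL/THR charge levels plus active flags and volume.

    Parameters
    ----------
    label : str
        One of :data:`MAP_LABELS`.
    mcl, thr : array of float, shape (12,)
        Charge levels in qu, non-negative; zero on inactive channels.
    active : array of bool, shape (12,)
    volume : float
        Processor volume in percent, in [0, 100].
    """

    label: str
    mcl: np.ndarray
    thr: np.ndarray
    active: np.ndarray
    volume: float = DEFAULT_VOLUME

    def __post_init__(self) -> None:
        self.mcl = np.asarray(self.mcl, dtype=float).copy()
        self.thr = np.asarray(self.thr, dtype=float).copy()
        self.active = np.asarray(self.active, dtype=bool).copy()
        for name in ("mcl", "thr", "active"):
            if getattr(self, name).shape != (N_CHANNELS,):
                raise ValueError(f"{name} must have shape ({N_CHANNELS},)")
        self.volume = float(self.volume)

    @property
    def n_channels(self) -> int:
        return N_CHANNELS

    def copy(self) -> "FittingMap":
        return FittingMap(
            label=self.label,
            mcl=self.mcl,
            thr=self.thr,
            active=self.active,
            volume=self.volume,
        )


class MapFormatError(ValueError):
    """Raised when a map file cannot be parsed."""


def validate_map(fitting_map: FittingMap, layout: ElectrodeLayout | None = None,
                 tol: float = 1e-9) -> list[str]:
    """Check all fitting-map invariants; return a list of violations.

    An empty list means the map is valid.  Each violation is a human-readable
    string naming the channel (1-based label) and the broken rule.  A channel
    count mismatch with the layout is a structural error and raises
    ``ValueError`` instead of being reported as a violation.
    """
    if layout is not None and layout.active.shape[0] != fitting_map.mcl.shape[0]:
        raise ValueError("map channel count does not match layout")

    violations: list[str] = []
    if fitting_map.label not in MAP_LABELS:
        violations.append(f"unknown map label {fitting_map.label!r}")
    if not 0.0 <= fitting_map.volume <= 100.0:
        violations.append(f"volume {fitting_map.volume} outside [0, 100]%")

    for i in range(N_CHANNELS):
        lab = channel_label(i)
        mcl, thr, act = fitting_map.mcl[i], fitting_map.thr[i], fitting_map.active[i]
        if mcl < 0 or thr < 0:
            violations.append(f"{lab}: negative charge level (mcl={mcl}, thr={thr})")
            continue
        if act:
            if thr > mcl + tol:
                violations.append(f"{lab}: THR {thr} exceeds MCL {mcl}")
            if abs(thr - THR_FRACTION * mcl) > tol:
                violations.append(
                    f"{lab}: THR {thr} is not {THR_FRACTION:.0%} of MCL {mcl}"
                )
        else:
            if mcl != 0.0 or thr != 0.0:
                violations.append(
                    f"{lab}: inactive channel carries non-zero levels "
                    f"(mcl={mcl}, thr={thr})"
                )
    return violations


def check_eligibility(layout: ElectrodeLayout) -> EligibilityReport:
    """Apply the participation rule: at least 10 of 12 channels active."""
    n = layout.n_active
    return EligibilityReport(n_active=n, eligible=n >= MIN_ACTIVE_FOR_ELIGIBILITY)


def set_thr_from_mcl(fitting_map: FittingMap) -> FittingMap:
    """Return a copy with THR set to 10% of the MCL on active channels.

    Inactive channels get ``thr = mcl = 0``.  All other fields are unchanged.
    """
    if np.any(fitting_map.mcl < 0):
        raise ValueError("MCL must be non-negative")
    out = fitting_map.copy()
    out.mcl = np.where(out.active, out.mcl, 0.0)
    out.thr = np.where(out.active, THR_FRACTION * out.mcl, 0.0)
    return out


def global_adjust(fitting_map: FittingMap, gain: float) -> FittingMap:
    """Scale the MCLs of all active channels by a common gain.

    This models the live-mode loudness adjustment: the audiologist scales the
    whole map up or down until the listener reports comfortable loudness.  The
    profile shape (ratios between channels) is preserved exactly; THR is
    recomputed with the 10% rule, and a pre-live label is promoted to its
    live variant (BurstMAP -> LiveBurstMAP, ECAPMAP -> LiveECAPMAP).
    """
    if not np.isfinite(gain) or gain <= 0:
        raise ValueError(f"gain must be positive, got {gain}")
    out = fitting_map.copy()
    out.mcl = np.where(out.active, out.mcl * gain, 0.0)
    out.label = _LIVE_PROMOTION.get(out.label, out.label)
    return set_thr_from_mcl(out)


def _map_to_dict(fitting_map: FittingMap) -> dict:
    return {
        "label": fitting_map.label,
        "volume_percent": fitting_map.volume,
        "channels": [
            {
                "id": channel_label(i),
                "active": bool(fitting_map.active[i]),
                "mcl_qu": float(fitting_map.mcl[i]),
                "thr_qu": float(fitting_map.thr[i]),
            }
            for i in range(N_CHANNELS)
        ],
    }


def _map_from_dict(data: dict, context: str = "<map>") -> FittingMap:
    for key in ("label", "volume_percent", "channels"):
        if key not in data:
            raise MapFormatError(f"{context}: missing required key {key!r}")
    channels = data["channels"]
    if len(channels) != N_CHANNELS:
        raise MapFormatError(
            f"{context}: expected {N_CHANNELS} channels, got {len(channels)}"
        )
    mcl = np.zeros(N_CHANNELS)
    thr = np.zeros(N_CHANNELS)
    active = np.zeros(N_CHANNELS, dtype=bool)
    seen: set[int] = set()
    for k, ch in enumerate(channels):
        for key in ("id", "active", "mcl_qu", "thr_qu"):
            if key not in ch:
                raise MapFormatError(
                    f"{context}: channel entry {k} missing key {key!r}"
                )
        try:
            idx = channel_index(ch["id"])
        except ValueError as exc:
            raise MapFormatError(f"{context}: channel entry {k}: {exc}") from exc
        if idx in seen:
            raise MapFormatError(f"{context}: duplicate channel id {ch['id']!r}")
        seen.add(idx)
        active[idx] = bool(ch["active"])
        mcl[idx] = float(ch["mcl_qu"])
        thr[idx] = float(ch["thr_qu"])
    return FittingMap(
        label=data["label"],
        mcl=mcl,
        thr=thr,
        active=active,
        volume=float(data["volume_percent"]),
    )


def write_map(path: str | Path, fitting_map: FittingMap) -> None:
    """Write a fitting map to a JSON file (one map per file)."""
    Path(path).write_text(json.dumps(_map_to_dict(fitting_map), indent=2) + "\n")


def read_map(path: str | Path) -> FittingMap:
    """Read a fitting map from a JSON file written by :func:`write_map`.

    Extra keys are accepted and ignored; missing required keys raise
    :class:`MapFormatError` with the file and field named.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MapFormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if not isinstance(data, dict):
        raise MapFormatError(f"{path}: expected a JSON object at top level")
    return _map_from_dict(data, context=str(path))
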