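"""Probe montage, block-design event schedules, and the in-memory recording container.

The montage mirrors a bedside continuous-wave acquisition: 8 sources and 15
detectors (8 of them short-channel detectors placed directly under each source),
with 3 cm long-channel and 0.8 cm short-channel source-detector separations.
Long channels carry a region-of-interest (ROI) label from
{frontal, sma, tongue_motor, parietal}; ROI labels, not optode coordinates,
drive all downstream logic (coordinates are schematic 10-10 positions).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError, ValidationError

ROI_LABELS = ("frontal", "sma", "tongue_motor", "parietal")

LONG_SEPARATION_CM = 3.0
SHORT_SEPARATION_CM = 0.8

#: wavelengths (nm) of the dual-wavelength acquisition
WAVELENGTHS = (760.0, 850.0)


@dataclass(frozen=True)
class Optode:
    label: str
    position: tuple[float, float, float]  # cm, schematic flattened-scalp frame


@dataclass(frozen=True)
class Channel:
    source: str
    detector: str
    separation: float  # cm
    roi: str | None  # None for short channels
    is_short: bool

    @property
    def name(self) -> str:
        return f"{self.source}_{self.detector}"


@dataclass(frozen=True)
class Probe:
    sources: tuple[Optode, ...]
    detectors: tuple[Optode, ...]
    short_detector_flags: tuple[bool, ...]
    channels: tuple[Channel, ...]

    def validate(self) -> None:
        det_short = dict(zip([d.label for d in self.detectors], self.short_detector_flags))
        for ch in self.channels:
            if ch.is_short:
                if ch.separation != SHORT_SEPARATION_CM:
                    raise ValidationError(
                        f"short channel {ch.name} has separation {ch.separation}, "
                        f"expected {SHORT_SEPARATION_CM} cm")
                if not det_short[ch.detector]:
                    raise ValidationError(f"short channel {ch.name} uses long detector")
            else:
                if ch.separation != LONG_SEPARATION_CM:
                    raise ValidationError(
                        f"long channel {ch.name} has separation {ch.separation}, "
                        f"expected {LONG_SEPARATION_CM} cm")
                if ch.roi not in ROI_LABELS:
                    raise ValidationError(f"long channel {ch.name} has no ROI label")
        # every source has exactly one short-channel detector
        by_source: dict[str, int] = {s.label: 0 for s in self.sources}
        for ch in self.channels:
            if ch.is_short:
                by_source[ch.source] += 1
        bad = [s for s, n in by_source.items() if n != 1]
        if bad:
            raise ValidationError(f"sources without exactly one short channel: {bad}")

    @property
    def long_channels(self) -> tuple[Channel, ...]:
        return tuple(ch for ch in self.channels if not ch.is_short)

    @property
    def short_channels(self) -> tuple[Channel, ...]:
        return tuple(ch for ch in self.channels if ch.is_short)

    def channel_index(self, name: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.name == name:
                return i
        raise KeyError(name)

    def optode_position(self, label: str) -> np.ndarray:
        for o in self.sources + self.detectors:
            if o.label == label:
                return np.asarray(o.position, float)
        raise KeyError(label)


# source label -> (10-10 label, position)
_SOURCES = {
    "S1": ("F3", (-5.0, 8.0, 0.0)),
    "S2": ("F4", (5.0, 8.0, 0.0)),
    "S3": ("FC1", (-2.0, 4.5, 0.0)),
    "S4": ("FC2", (2.0, 4.5, 0.0)),
    "S5": ("FC5", (-6.5, 1.5, 0.0)),
    "S6": ("FC6", (6.5, 1.5, 0.0)),
    "S7": ("P3", (-4.0, -5.5, 0.0)),
    "S8": ("P4", (4.0, -5.5, 0.0)),
}

_LONG_DETECTORS = {
    "D1": (-3.6, 6.2, 0.0),
    "D2": (3.6, 6.2, 0.0),
    "D3": (0.0, 5.8, 0.0),
    "D4": (-6.8, 4.5, 0.0),
    "D5": (6.8, 4.5, 0.0),
    "D6": (-4.8, -2.0, 0.0),
    "D7": (4.8, -2.0, 0.0),
}

# (source, detector, roi); two long channels per ROI per hemisphere
_LONG_CHANNELS = [
    ("S1", "D1", "frontal"), ("S1", "D3", "frontal"),
    ("S2", "D2", "frontal"), ("S2", "D3", "frontal"),
    ("S3", "D1", "sma"), ("S3", "D3", "sma"),
    ("S4", "D2", "sma"), ("S4", "D3", "sma"),
    ("S5", "D4", "tongue_motor"), ("S5", "D6", "tongue_motor"),
    ("S6", "D5", "tongue_motor"), ("S6", "D7", "tongue_motor"),
    ("S7", "D6", "parietal"), ("S7", "D7", "parietal"),
    ("S8", "D6", "parietal"), ("S8", "D7", "parietal"),
]


def default_montage() -> Probe:
    """Default 8-source / 15-detector montage.

    16 long channels (two per ROI per hemisphere) over frontal cortex,
    supplementary motor area, tongue motor homunculi and parietal cortex,
    plus 8 short channels, one under each source.
    """
    sources = tuple(Optode(lab, pos) for lab, (_, pos) in _SOURCES.items())
    long_dets = [Optode(lab, pos) for lab, pos in _LONG_DETECTORS.items()]
    short_dets = [Optode(f"D{8 + i}", pos) for i, (_, (_, pos)) in enumerate(_SOURCES.items())]
    detectors = tuple(long_dets + short_dets)
    flags = tuple([False] * len(long_dets) + [True] * len(short_dets))

    channels = [Channel(s, d, LONG_SEPARATION_CM, roi, False) for s, d, roi in _LONG_CHANNELS]
    for i, src in enumerate(_SOURCES):
        channels.append(Channel(src, f"D{8 + i}", SHORT_SEPARATION_CM, None, True))
    probe = Probe(sources, detectors, flags, tuple(channels))
    probe.validate()
    return probe


@dataclass(frozen=True)
class Epoch:
    onset: float  # s from recording start
    duration: float  # s
    condition: str  # "task" or "rest"

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class EventSchedule:
    """Time-ordered, non-overlapping task/rest epochs; intervals are [onset, onset+duration)."""

    epochs: tuple[Epoch, ...]
    total_duration: float

    def validate(self) -> None:
        prev_end = 0.0
        for ep in self.epochs:
            if ep.condition not in ("task", "rest"):
                raise ValidationError(f"unknown condition {ep.condition!r}")
            if ep.duration <= 0:
                raise ValidationError("epoch with non-positive duration")
            if ep.onset < prev_end - 1e-9:
                raise ValidationError("overlapping or unordered epochs")
            prev_end = ep.offset
        if prev_end > self.total_duration + 1e-9:
            raise ValidationError("epochs extend beyond total_duration")

    @property
    def task_epochs(self) -> tuple[Epoch, ...]:
        return tuple(ep for ep in self.epochs if ep.condition == "task")


def build_block_design(n_blocks: int = 3, reps: int = 8, task_s: float = 15.0,
                       rest_s: float = 15.0, gap_s: float = 0.0,
                       lead_in_s: float = 0.0) -> EventSchedule:
    """Build a block design of ``n_blocks`` blocks of ``reps`` (task, rest) cycles.

    Within a block task and rest alternate starting with task; blocks are
    separated by a rest gap of ``gap_s``. The default 3 x 8 x (15 s + 15 s)
    design yields 24 task epochs over 720 s (plus gaps / lead-in).
    """
    for name, v in [("n_blocks", n_blocks), ("reps", reps),
                    ("task_s", task_s), ("rest_s", rest_s)]:
        if v <= 0:
            raise ParameterError(f"{name} must be positive, got {v}")
    for name, v in [("gap_s", gap_s), ("lead_in_s", lead_in_s)]:
        if v < 0:
            raise ParameterError(f"{name} must be non-negative, got {v}")

    epochs: list[Epoch] = []
    t = 0.0
    if lead_in_s > 0:
        epochs.append(Epoch(0.0, lead_in_s, "rest"))
        t = lead_in_s
    for b in range(n_blocks):
        if b > 0 and gap_s > 0:
            epochs.append(Epoch(t, gap_s, "rest"))
            t += gap_s
        for _ in range(reps):
            epochs.append(Epoch(t, task_s, "task"))
            t += task_s
            epochs.append(Epoch(t, rest_s, "rest"))
            t += rest_s
    sched = EventSchedule(tuple(epochs), t)
    sched.validate()
    return sched


@dataclass
class Recording:
    """A dual-wavelength intensity recording with montage, events and metadata.

    ``intensity`` has shape (n_samples, n_channels, 2) in arbitrary units with
    the channel axis aligned to ``probe.channels`` and the wavelength axis
    ordered (760, 850) nm.
    """

    probe: Probe
    intensity: np.ndarray  # (T, n_channels, 2), a.u., strictly positive
    wavelengths: tuple[float, float]
    sampling_rate: float  # Hz
    events: EventSchedule
    subject_id: str = "sub-01"
    session_index: int = 1
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.probe.validate()
        self.events.validate()
        inten = np.asarray(self.intensity)
        if inten.ndim != 3 or inten.shape[1] != len(self.probe.channels) or inten.shape[2] != 2:
            raise ValidationError(
                f"intensity shape {inten.shape} does not match "
                f"(n_samples, {len(self.probe.channels)}, 2)")
        if len(self.wavelengths) != 2:
            raise ValidationError("exactly two wavelengths required")
        if not np.all(np.isfinite(inten)) or np.any(inten <= 0):
            raise ValidationError("intensity must be finite and strictly positive")
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if self.session_index not in (1, 2, 3):
            raise ValidationError("session_index must be in {1, 2, 3}")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)
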