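"""Core spike-train types, file I/O and elementary rate/ISI extraction.

Times are stored in seconds throughout; interspike intervals (ISIs) are
returned in milliseconds, the unit in which all patterning statistics are
quoted. All bins and windows are half-open ``[a, b)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Group",
    "CellClass",
    "EventLabel",
    "EventMarker",
    "RecordingMeta",
    "SpikeTrain",
    "RateSeries",
    "AnalysisConfig",
    "ValidationError",
    "InsufficientDataError",
    "load_spike_train",
    "save_spike_train",
    "extract_isis",
    "bin_rate",
    "mean_rate",
]


class ValidationError(ValueError):
    """Raised when an input file or object violates a structural invariant."""


class InsufficientDataError(ValueError):
    """Raised when a record is too short/sparse for the requested analysis.

    Distinct from :class:`ValidationError` so callers can tell a malformed
    file from a well-formed but inadequate one.
    """


class Group(str, enum.Enum):
    """Animal treatment group: euhydrated, salt-loaded, rehydrated."""

    EU = "EU"
    SL = "SL"
    RE = "RE"


class CellClass(str, enum.Enum):
    OT = "OT"
    VP_CONT = "VP_cont"
    VP_PHASIC = "VP_phasic"
    UNDETERMINED = "undetermined"


class EventLabel(str, enum.Enum):
    CCK = "CCK"
    PE = "PE"
    PEG = "PEG"
    PUMP_ON = "pump_on"
    PUMP_OFF = "pump_off"
    STIM_PULSE = "stim_pulse"
    OTHER = "other"


@dataclass(frozen=True)
class EventMarker:
    label: EventLabel
    time: float  # s


@dataclass
class RecordingMeta:
    cell_id: str = ""
    animal_id: str = ""
    group: Group = Group.EU
    cell_class: CellClass = CellClass.UNDETERMINED
    events: list[EventMarker] = field(default_factory=list)

    def event_time(self, label: EventLabel | str) -> float:
        """Time of the first event with the given label."""
        label = EventLabel(label)
        for ev in self.events:
            if ev.label == label:
                return ev.time
        raise KeyError(f"no event with label {label.value!r}")


@dataclass
class SpikeTrain:
    """Ordered spike arrival times over a recording of known duration.

    Parameters
    ----------
    times
        Spike times in seconds, strictly ascending, all ``>= 0`` and
        ``<= duration``.
    duration
        Record span in seconds. If omitted, the last spike time is used.
    resolution
        Acquisition resolution in seconds (deposited recordings are timed
        at 0.1 ms). Input times are never rounded.
    """

    times: np.ndarray
    duration: float = 0.0
    resolution: float = 1e-4

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValidationError("spike times must be a 1-D sequence")
        if self.times.size and self.times[0] < 0:
            raise ValidationError("spike times must be non-negative")
        d = np.diff(self.times)
        if np.any(d <= 0):
            row = int(np.argmax(d <= 0)) + 1
            raise ValidationError(
                f"spike times must be strictly ascending (violation at row {row})"
            )
        if self.duration <= 0:
            self.duration = float(self.times[-1]) if self.times.size else 0.0
        if self.duration <= 0:
            raise ValidationError("duration must be positive")
        if self.times.size and self.times[-1] > self.duration:
            raise ValidationError("spike times exceed the stated duration")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def in_window(self, window: tuple[float, float]) -> np.ndarray:
        """Spike times within the half-open window ``[a, b)``."""
        a, b = window
        return self.times[(self.times >= a) & (self.times < b)]


@dataclass
class RateSeries:
    """Contiguous half-open-binned firing rates, in spikes/s per bin."""

    bin_width: float
    start: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def bin_centres(self) -> np.ndarray:
        return self.start + (np.arange(self.values.size) + 0.5) * self.bin_width


@dataclass
class AnalysisConfig:
    """Numeric constants used throughout the pipeline.

    Defaults are the constants of the original analysis protocol: 10-ms
    hazard bins with the peak sought below 90 ms and the asymptote averaged
    over 140–290 ms; burst criteria of >=5 s span, >=20 spikes, intraburst
    ISIs <=1 s, >5 s between bursts; 5-min response windows; 0.3 spikes/s
    unresponsive threshold; 5-min infusion-line lag; 20–30 min osmotic and
    30–45 min hypovolaemia response windows; 40-ms peristimulus bins; the
    spike-triggered-average baseline measured 10–15 ms before the spike.
    """

    hazard_bin: float = 10.0  # ms
    hazard_peak_limit: float = 90.0  # ms
    asymptote_window: tuple[float, float] = (140.0, 290.0)  # ms
    mode_bin: float = 1.0  # ms
    mode_min_peak_count: int = 5
    burst_min_duration: float = 5.0  # s
    burst_min_spikes: int = 20
    burst_max_isi: float = 1.0  # s
    interburst_min_silence: float = 5.0  # s
    response_window: float = 5.0  # min
    unresponsive_threshold: float = 0.3  # spikes/s
    pump_lag: float = 5.0  # min
    osmotic_response_window: tuple[float, float] = (20.0, 30.0)  # min
    peg_response_window: tuple[float, float] = (30.0, 45.0)  # min
    psth_bin: float = 40.0  # ms
    sta_baseline_window: tuple[float, float] = (-15.0, -10.0)  # ms
    clean_spike_gap: float = 100.0  # ms
    phasic_rate_threshold: float = 4.0  # spikes/s
    silence_rate_threshold: float = 0.5  # spikes/s: "near silence" ceiling
    osmotic_basal_window_cont: float = 5.0  # min
    osmotic_basal_window_phasic: float = 10.0  # min

    def __post_init__(self) -> None:
        for name in (
            "hazard_bin", "hazard_peak_limit", "mode_bin", "burst_min_duration",
            "burst_max_isi", "interburst_min_silence", "response_window",
            "unresponsive_threshold", "pump_lag", "psth_bin", "clean_spike_gap",
            "phasic_rate_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        for name in ("asymptote_window", "osmotic_response_window",
                     "peg_response_window", "sta_baseline_window"):
            a, b = getattr(self, name)
            if not a < b:
                raise ValidationError(f"{name} must be an ordered window")


# ---------------------------------------------------------------------------
# I/O: spike-time CSV (header `time_s`, one float per row) + YAML sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def load_spike_train(path: str | Path) -> tuple[SpikeTrain, RecordingMeta]:
    """Read a spike-time CSV and its YAML sidecar (same stem, ``.yaml``).

    The CSV has a single header line ``time_s`` followed by one float per
    row. The sidecar, when present, supplies cell/animal identity, group,
    cell class, the record duration and event markers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    times: list[float] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if header != "time_s":
            raise ValidationError(f"{path}: expected header 'time_s', got {header!r}")
        for i, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            try:
                times.append(float(line))
            except ValueError as exc:
                raise ValidationError(f"{path}: row {i}: not a number: {line!r}") from exc

    meta = RecordingMeta()
    duration = 0.0
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        meta = RecordingMeta(
            cell_id=str(raw.get("cell_id", path.stem)),
            animal_id=str(raw.get("animal_id", "")),
            group=Group(raw.get("group", "EU")),
            cell_class=CellClass(raw.get("cell_class", "undetermined")),
            events=[
                EventMarker(EventLabel(ev["label"]), float(ev["time_s"]))
                for ev in raw.get("events", [])
            ],
        )
        duration = float(raw.get("duration_s", 0.0))
    else:
        meta.cell_id = path.stem

    try:
        train = SpikeTrain(np.asarray(times), duration=duration)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    for ev in meta.events:
        if not 0 <= ev.time <= train.duration:
            raise ValidationError(
                f"{path}: event {ev.label.value}@{ev.time}s outside record"
            )
    return train, meta


def save_spike_train(
    path: str | Path, train: SpikeTrain, meta: RecordingMeta | None = None
) -> None:
    """Write the spike-time CSV dialect and, if meta is given, the sidecar."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("time_s\n")
        # 0.1-ms resolution -> 4 decimals reproduces times exactly
        decimals = max(0, int(np.ceil(-np.log10(train.resolution))))
        for t in train.times:
            fh.write(f"{t:.{decimals}f}\n")
    if meta is not None:
        doc = {
            "cell_id": meta.cell_id,
            "animal_id": meta.animal_id,
            "group": meta.group.value,
            "cell_class": meta.cell_class.value,
            "duration_s": float(train.duration),
            "events": [
                {"label": ev.label.value, "time_s": float(ev.time)}
                for ev in meta.events
            ],
        }
        with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Elementary extraction
# ---------------------------------------------------------------------------

def extract_isis(
    train: SpikeTrain, window: tuple[float, float] | None = None
) -> np.ndarray:
    """Interspike intervals in milliseconds, order preserved.

    Raises :class:`InsufficientDataError` if fewer than two spikes fall in
    the window.
    """
    times = train.times if window is None else train.in_window(window)
    if times.size < 2:
        raise InsufficientDataError(
            f"need >=2 spikes to form ISIs, got {times.size}"
        )
    return np.diff(times) * 1000.0


def bin_rate(
    train: SpikeTrain,
    bin_width: float,
    start: float = 0.0,
    end: float | None = None,
) -> RateSeries:
    """Firing rate in contiguous half-open bins of ``bin_width`` seconds.

    The trailing partial bin (if ``end - start`` is not a multiple of the
    width) is dropped.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if end is None:
        end = train.duration
    n_bins = int(np.floor((end - start) / bin_width + 1e-12))
    if n_bins <= 0:
        return RateSeries(bin_width, start, np.zeros(0))
    edges = start + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(train.times, bins=edges)
    return RateSeries(bin_width, start, counts / bin_width)


def mean_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Mean firing rate (spikes/s) over the half-open window ``[a, b)``."""
    a, b = window
    if not b > a:
        raise ValidationError("window must have positive length")
    return train.in_window(window).size / (b - a)


def isis_to_times(isis_ms: Sequence[float], first_spike: float = 0.0) -> np.ndarray:
    """Inverse of :func:`extract_isis`: cumulative-sum ISIs back to times (s)."""
    isis = np.asarray(isis_ms, dtype=float) / 1000.0
    return first_spike + np.concatenate([[0.0], np.cumsum(isis)])
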