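"""Burst segmentation of phasic firing.

A burst is a period of >=5 s containing >=20 spikes separated by ISIs
<=1 s, with >5 s between bursts. Because the ISI criterion alone can leave
1–5 s gaps between qualifying spike chains — which would violate the >5 s
interburst rule — qualifying chains separated by gaps of <=5 s are merged,
with the gap included in the burst span. Statistics are computed over
complete bursts only (those bounded by >=5 s of burst-free record on both
sides), mirroring the restriction to complete bursts and complete
interburst intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AnalysisConfig, InsufficientDataError, SpikeTrain, mean_rate

__all__ = [
    "Burst",
    "BurstStats",
    "BurstSegmentation",
    "segment_bursts",
    "burst_stats",
    "classify_phasic",
]


@dataclass
class Burst:
    start: float  # s, first spike
    end: float  # s, last spike
    n_spikes: int
    complete: bool = True

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def intraburst_rate(self) -> float:
        return self.n_spikes / self.duration if self.duration > 0 else np.nan


@dataclass
class BurstStats:
    mean_burst_duration: float  # s
    mean_silence_duration: float  # s
    intraburst_rate: float  # spikes/s, pooled over complete bursts
    spikes_per_burst: float
    n_complete_bursts: int
    n_complete_silences: int


@dataclass
class BurstSegmentation:
    bursts: list[Burst] = field(default_factory=list)
    silences: list[tuple[float, float]] = field(default_factory=list)

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def complete_bursts(self) -> list[Burst]:
        return [b for b in self.bursts if b.complete]


def _chains(times: np.ndarray, max_isi: float) -> list[tuple[int, int]]:
    """Maximal runs of spikes whose consecutive ISIs are all <= max_isi.

    Returns (first_index, last_index) pairs, inclusive.
    """
    if times.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(times) > max_isi)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [times.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def segment_bursts(
    train: SpikeTrain, cfg: AnalysisConfig | None = None
) -> BurstSegmentation:
    """Identify bursts and interburst silences in a spike train.

    Steps: (i) chain spikes with consecutive ISIs <= ``burst_max_isi``;
    (ii) chains spanning >= ``burst_min_duration`` with >=
    ``burst_min_spikes`` spikes become candidates; (iii) candidates
    separated by gaps <= ``interburst_min_silence`` are merged, gap
    included; (iv) remaining gaps between bursts are silences (all
    > ``interburst_min_silence`` by construction). Bursts not bounded by
    that much burst-free record on both sides are marked incomplete.
    """
    cfg = cfg or AnalysisConfig()
    t = train.times
    candidates: list[tuple[float, float, int]] = []
    for i0, i1 in _chains(t, cfg.burst_max_isi):
        span = t[i1] - t[i0]
        n = i1 - i0 + 1
        if span >= cfg.burst_min_duration and n >= cfg.burst_min_spikes:
            candidates.append((float(t[i0]), float(t[i1]), n))

    # merge candidates across gaps <= interburst_min_silence; spikes falling
    # in the absorbed gap are counted into the merged burst
    merged: list[tuple[float, float]] = []
    for start, end, _ in candidates:
        if merged and start - merged[-1][1] <= cfg.interburst_min_silence:
            merged[-1] = (merged[-1][0], end)
        else:
            merged.append((start, end))

    bursts: list[Burst] = []
    for k, (start, end) in enumerate(merged):
        n = int(np.sum((t >= start) & (t <= end)))
        prev_end = merged[k - 1][1] if k > 0 else 0.0
        next_start = merged[k + 1][0] if k + 1 < len(merged) else train.duration
        complete = (
            start - prev_end >= cfg.interburst_min_silence
            and next_start - end >= cfg.interburst_min_silence
        )
        # an opening/closing burst is complete only if the record extends
        # far enough beyond it
        if k == 0 and start < cfg.interburst_min_silence:
            complete = False
        if k == len(merged) - 1 and train.duration - end < cfg.interburst_min_silence:
            complete = False
        bursts.append(Burst(start, end, n, complete))

    silences = [
        (bursts[k].end, bursts[k + 1].start) for k in range(len(bursts) - 1)
    ]
    return BurstSegmentation(bursts=bursts, silences=silences)


def burst_stats(seg: BurstSegmentation, train: SpikeTrain | None = None) -> BurstStats:
    """Mean burst/silence durations, pooled intraburst rate and spikes per
    burst over complete bursts. Raises when there is no complete burst."""
    complete = seg.complete_bursts()
    if not complete:
        raise InsufficientDataError(
            "no complete bursts; a longer record is needed for burst statistics"
        )
    durs = np.array([b.duration for b in complete])
    counts = np.array([b.n_spikes for b in complete])
    sil = np.array([b - a for a, b in seg.silences]) if seg.silences else np.array([])
    return BurstStats(
        mean_burst_duration=float(durs.mean()),
        mean_silence_duration=float(sil.mean()) if sil.size else np.nan,
        intraburst_rate=float(counts.sum() / durs.sum()),
        spikes_per_burst=float(counts.mean()),
        n_complete_bursts=len(complete),
        n_complete_silences=int(sil.size),
    )


def classify_phasic(
    train: SpikeTrain, cfg: AnalysisConfig | None = None
) -> bool | None:
    """Phasic iff segmentation yields >=2 bursts firing above the phasic
    rate threshold (4 spikes/s within bursts) separated by >=1 period of
    near silence (interburst rate below ``silence_rate_threshold``; an
    irregular continuous train can produce burst-shaped chains, but its
    interburst gaps still contain spikes at the background rate).

    Returns None (undetermined) for records shorter than 10 min.
    """
    cfg = cfg or AnalysisConfig()
    if train.duration < 600.0:
        return None
    seg = segment_bursts(train, cfg)
    fast = [b for b in seg.bursts if b.intraburst_rate > cfg.phasic_rate_threshold]
    quiet = [
        (a, b) for a, b in seg.silences
        if mean_rate(train, (a, b)) < cfg.silence_rate_threshold
    ]
    return len(fast) >= 2 and len(quiet) >= 1
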