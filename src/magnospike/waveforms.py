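"""Spike-triggered averaging of extracellular voltage.

Averages are built on a fixed grid (default -20 to +100 ms at the native
0.1-ms sampling), then aligned to the maximum negative deflection (t0),
zeroed to a baseline measured 10–15 ms before the spike, normalized to
unit spike height at t0 and sign-flipped so the spike is positive-going
(recorded waveforms are negative-going; presentation convention is
depolarizing-up).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InsufficientDataError, ValidationError

__all__ = [
    "VoltageTrace",
    "WaveformAverage",
    "spike_triggered_average",
    "normalize_waveform",
    "clean_spike_filter",
    "population_waveform",
]


@dataclass
class VoltageTrace:
    samples: np.ndarray
    sampling_rate: float = 10_000.0  # Hz
    t0: float = 0.0  # s, time of first sample

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")


@dataclass
class WaveformAverage:
    grid: np.ndarray  # ms relative to the alignment point
    mean: np.ndarray
    sd: np.ndarray
    n_spikes: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)


def spike_triggered_average(
    trace: VoltageTrace,
    spikes: np.ndarray,
    window: tuple[float, float] = (-20.0, 100.0),
) -> WaveformAverage:
    """Mean and SD of spike-aligned voltage segments.

    ``window`` is in ms relative to each spike. Spikes whose window falls
    outside the trace are dropped; at least one must remain (averages from
    fewer than ~1000 spikes are noisy but permitted).
    """
    lo_ms, hi_ms = window
    dt = 1.0 / trace.sampling_rate
    lo = int(round(lo_ms / 1000.0 / dt))
    hi = int(round(hi_ms / 1000.0 / dt))
    idx = np.round((np.asarray(spikes, dtype=float) - trace.t0) / dt).astype(int)
    ok = (idx + lo >= 0) & (idx + hi < trace.samples.size)
    idx = idx[ok]
    if idx.size == 0:
        raise InsufficientDataError("no spike with a full window inside the trace")
    offsets = np.arange(lo, hi + 1)
    segs = trace.samples[idx[:, None] + offsets[None, :]]
    grid = offsets * dt * 1000.0
    return WaveformAverage(
        grid=grid,
        mean=segs.mean(axis=0),
        sd=segs.std(axis=0, ddof=1) if idx.size > 1 else np.zeros(grid.size),
        n_spikes=int(idx.size),
    )


def normalize_waveform(
    avg: WaveformAverage,
    baseline_window: tuple[float, float] = (-15.0, -10.0),
) -> WaveformAverage:
    """Align to the maximum negative deflection (t0), zero to the
    pre-spike baseline, scale to unit spike height and flip positive-going.

    Raises on an already-normalized or flat input.
    """
    if avg.normalized:
        raise ValidationError("waveform is already normalized")
    i0 = int(np.argmin(avg.mean))
    grid = avg.grid - avg.grid[i0]
    b_lo, b_hi = baseline_window
    mask = (grid >= b_lo) & (grid < b_hi)
    if not mask.any():
        raise ValidationError("baseline window outside waveform grid")
    baseline = float(avg.mean[mask].mean())
    centred = avg.mean - baseline
    height = centred[i0]
    if height == 0:
        raise ValidationError("flat waveform: no deflection to normalize by")
    # dividing by the (negative) trough both scales to 1 at t0 and flips sign
    scale = height
    return WaveformAverage(
        grid=grid,
        mean=centred / scale,
        sd=avg.sd / abs(scale),
        n_spikes=avg.n_spikes,
        normalized=True,
    )


def clean_spike_filter(spikes: np.ndarray, gap_ms: float = 100.0) -> np.ndarray:
    """Spikes not followed by another spike within ``gap_ms``.

    The last spike is always kept.
    """
    s = np.asarray(spikes, dtype=float)
    if s.size <= 1:
        return s.copy()
    keep = np.concatenate([np.diff(s) > gap_ms / 1000.0, [True]])
    return s[keep]


def population_waveform(
    avgs: list[WaveformAverage],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unweighted across-cell mean and SD of normalized averages.

    All inputs must be normalized and share a common grid after alignment;
    they are trimmed to the overlapping grid range. Returns
    ``(grid, mean, sd)``.
    """
    if not avgs:
        raise InsufficientDataError("no waveforms to average")
    if any(not a.normalized for a in avgs):
        raise ValidationError("population averaging requires normalized waveforms")
    step = np.diff(avgs[0].grid[:2])[0]
    for a in avgs:
        if abs(np.diff(a.grid[:2])[0] - step) > 1e-9:
            raise ValidationError("mismatched waveform grids")
    lo = max(a.grid[0] for a in avgs)
    hi = min(a.grid[-1] for a in avgs)
    if hi <= lo:
        raise ValidationError("waveform grids do not overlap")
    n = int(round((hi - lo) / step)) + 1
    grid = lo + np.arange(n) * step
    mat = np.empty((len(avgs), n))
    for i, a in enumerate(avgs):
        start = int(round((lo - a.grid[0]) / step))
        mat[i] = a.mean[start : start + n]
    sd = mat.std(axis=0, ddof=1) if len(avgs) > 1 else np.zeros(n)
    return grid, mat.mean(axis=0), sd
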