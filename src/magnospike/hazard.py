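"""Hazard-function estimate of post-spike excitability.

The estimator works on ISIs in 10-ms bins:

    hazard in bin [t, t+10) = 100 * (#ISIs in bin) / (#ISIs > t+10 ms)

The maximum over bins below 90 ms ("peak") marks the time of greatest
post-spike depolarization; the mean over 140–290 ms estimates the
asymptote; their difference ("peak hazard") indexes the amplitude of the
depolarizing afterpotential (DAP). The denominator follows the formula
verbatim — intervals strictly greater than the bin's *right* edge — with a
conventional at-risk (``>= t``) variant available but never default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, InsufficientDataError

__all__ = [
    "HazardFunction",
    "HazardSummary",
    "hazard_function",
    "hazard_summary",
    "peak_time_binned_aggregate",
]


@dataclass
class HazardFunction:
    bin_width: float  # ms
    values: np.ndarray  # % per bin, defined for bins with positive denominator
    valid_up_to: float  # ms: right edge of the last computed bin

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.values.size + 1) * self.bin_width


@dataclass
class HazardSummary:
    max_hazard: float  # %
    peak_time: float  # ms, left edge of the maximal bin
    asymptote: float  # %
    peak_hazard: float  # % == max_hazard - asymptote
    defined: bool = True


def hazard_function(
    isis_ms: np.ndarray,
    bin_width: float = 10.0,
    conventional: bool = False,
) -> HazardFunction:
    """Per-bin hazard (%) from an ISI sample.

    Computation stops at the first bin whose denominator is zero;
    ``valid_up_to`` records the right edge of the last bin computed.

    With ``conventional=True`` the denominator is the number of intervals
    at risk at the bin's *left* edge (``#ISIs >= t``), the textbook
    discrete-hazard form.
    """
    x = np.asarray(isis_ms, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("hazard needs at least one ISI")
    values: list[float] = []
    t = 0.0
    while True:
        right = t + bin_width
        numer = int(np.sum((x >= t) & (x < right)))
        denom = int(np.sum(x >= t)) if conventional else int(np.sum(x > right))
        if denom == 0:
            break
        values.append(100.0 * numer / denom)
        t = right
    return HazardFunction(bin_width, np.array(values), valid_up_to=t)


def hazard_summary(
    hz: HazardFunction, cfg: AnalysisConfig | None = None
) -> HazardSummary:
    """Peak (below 90 ms), asymptote (mean over 140–290 ms) and their
    difference. Flagged undefined if the hazard is not valid through the
    asymptote window."""
    cfg = cfg or AnalysisConfig()
    a_lo, a_hi = cfg.asymptote_window
    if hz.valid_up_to < a_hi:
        return HazardSummary(np.nan, np.nan, np.nan, np.nan, defined=False)
    w = hz.bin_width
    # "ISIs < 90 ms": bins whose right edge <= 90 ms
    n_peak = int(np.floor(cfg.hazard_peak_limit / w + 1e-9))
    peak_vals = hz.values[:n_peak]
    i_max = int(np.argmax(peak_vals))
    max_hazard = float(peak_vals[i_max])
    # bins [140,150) ... [280,290): left edges in [a_lo, a_hi)
    lo = int(np.floor(a_lo / w + 1e-9))
    hi = int(np.floor(a_hi / w + 1e-9))
    asymptote = float(np.mean(hz.values[lo:hi]))
    return HazardSummary(
        max_hazard=max_hazard,
        peak_time=float(i_max * w),
        asymptote=asymptote,
        peak_hazard=max_hazard - asymptote,
    )


def peak_time_binned_aggregate(
    cells: list[tuple[HazardSummary, str]],
    bin_width: float = 10.0,
) -> dict[str, dict[float, tuple[float, float, int]]]:
    """Group cells by peak-time bin and report per-bin peak-hazard mean/SD.

    Returns ``{group: {bin_left_edge_ms: (mean, sd, n)}}``. Bins holding a
    single cell report SD = 0 with n = 1 so they can be flagged downstream.
    """
    out: dict[str, dict[float, tuple[float, float, int]]] = {}
    buckets: dict[tuple[str, float], list[float]] = {}
    for summ, group in cells:
        if not summ.defined:
            continue
        edge = float(np.floor(summ.peak_time / bin_width) * bin_width)
        buckets.setdefault((group, edge), []).append(summ.peak_hazard)
    for (group, edge), vals in sorted(buckets.items()):
        arr = np.asarray(vals)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        out.setdefault(group, {})[edge] = (float(arr.mean()), sd, int(arr.size))
    return out
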