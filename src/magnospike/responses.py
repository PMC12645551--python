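"""Quantification of responses to CCK, phenylephrine, hypertonic infusion,
polyethylene-glycol hypovolaemia and electrical stimulation, and CCK-based
cell classification.

Conventions: CCK and PE responses compare the 5 min after injection with
the 5 min before (delta and percent of basal); the osmotic stimulus onset
is the pump switch-on plus a 5-min line lag, with the response quantified
20–30 min after onset as change from basal and, across the infusion, as a
least-squares slope through the origin of rate change against mmol NaCl
infused; the hypovolaemia response uses the 30–45 min post-injection
window; peristimulus-time histograms count spikes in 40-ms bins as a
percentage of pre-stimulation counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AnalysisConfig,
    CellClass,
    InsufficientDataError,
    RateSeries,
    SpikeTrain,
    bin_rate,
    mean_rate,
)

__all__ = [
    "ResponseResult",
    "OsmoticResponse",
    "PSTH",
    "cck_response",
    "pe_response",
    "peg_response",
    "osmotic_response",
    "classify_cell",
    "psth",
    "infused_mmol_at",
]

# hypertonic infusion schedule: 2 M NaCl at 26 uL/min
INFUSION_MOLARITY = 2.0  # mol/L
INFUSION_RATE_UL_MIN = 26.0


@dataclass
class ResponseResult:
    basal_rate: float  # spikes/s
    response_rate: float  # spikes/s
    delta: float  # spikes/s == response - basal
    percent_of_basal: float | None  # 100*response/basal; None when basal == 0
    windows: tuple[tuple[float, float], tuple[float, float]]  # (basal, response) in s


@dataclass
class OsmoticResponse:
    series: RateSeries  # 30-s-bin rates with basal subtracted
    basal_rate: float  # spikes/s
    response_20_30: float  # spikes/s change from basal
    slope_per_mmol: float  # spikes/s per mmol infused
    onset: float  # s, pump_on + lag


@dataclass
class PSTH:
    bin_width: float  # ms
    values: np.ndarray  # % of mean pre-stimulation count per bin
    n_stimuli: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def _windowed_delta(
    train: SpikeTrain,
    t_event: float,
    pre: tuple[float, float],
    post: tuple[float, float],
) -> ResponseResult:
    (a0, a1), (b0, b1) = pre, post
    if a0 < 0 or b1 > train.duration:
        raise InsufficientDataError(
            f"record [{0}, {train.duration:.0f}] s does not cover windows "
            f"[{a0:.0f},{a1:.0f}) and [{b0:.0f},{b1:.0f}) s"
        )
    assert a1 <= b0, "basal and response windows must not overlap"
    basal = mean_rate(train, (a0, a1))
    resp = mean_rate(train, (b0, b1))
    return ResponseResult(
        basal_rate=basal,
        response_rate=resp,
        delta=resp - basal,
        percent_of_basal=(100.0 * resp / basal) if basal > 0 else None,
        windows=((a0, a1), (b0, b1)),
    )


def cck_response(
    train: SpikeTrain, t_inj: float, cfg: AnalysisConfig | None = None
) -> ResponseResult:
    """Change in mean firing rate in the 5 min after CCK injection relative
    to the 5 min before."""
    cfg = cfg or AnalysisConfig()
    w = cfg.response_window * 60.0
    return _windowed_delta(train, t_inj, (t_inj - w, t_inj), (t_inj, t_inj + w))


def pe_response(
    train: SpikeTrain, t_inj: float, cfg: AnalysisConfig | None = None
) -> ResponseResult:
    """Response to phenylephrine: same windows as CCK, reported primarily
    as the percentage of basal rate."""
    return cck_response(train, t_inj, cfg)


def peg_response(
    train: SpikeTrain, t_inj: float, cfg: AnalysisConfig | None = None
) -> ResponseResult:
    """Hypovolaemia response: rate 30–45 min after PEG injection minus the
    basal rate (default 10-min basal window)."""
    cfg = cfg or AnalysisConfig()
    lo, hi = (m * 60.0 for m in cfg.peg_response_window)
    basal_span = 10.0 * 60.0
    return _windowed_delta(
        train, t_inj, (t_inj - basal_span, t_inj), (t_inj + lo, t_inj + hi)
    )


def classify_cell(
    delta: float, phasic: bool, cfg: AnalysisConfig | None = None
) -> CellClass:
    """CCK-based identification: phasic cells are vasopressin cells
    regardless of the CCK response; otherwise excitation >0.3 spikes/s
    marks an oxytocin cell, inhibition >0.3 spikes/s a continuous
    vasopressin cell, and |delta| <= 0.3 spikes/s is unresponsive
    (undetermined identity)."""
    cfg = cfg or AnalysisConfig()
    if phasic:
        return CellClass.VP_PHASIC
    thr = cfg.unresponsive_threshold
    if delta > thr:
        return CellClass.OT
    if delta < -thr:
        return CellClass.VP_CONT
    return CellClass.UNDETERMINED


def infused_mmol_at(elapsed_min: np.ndarray | float) -> np.ndarray | float:
    """mmol NaCl delivered after ``elapsed_min`` minutes of the standard
    2 M x 26 uL/min infusion (1.56 mmol by 30 min)."""
    return INFUSION_MOLARITY * INFUSION_RATE_UL_MIN * 1e-3 * np.asarray(
        elapsed_min, dtype=float
    )


def osmotic_response(
    train: SpikeTrain,
    pump_on: float,
    cfg: AnalysisConfig | None = None,
    phasic: bool = False,
    infusion_duration_min: float = 30.0,
) -> OsmoticResponse:
    """Response to i.v. hypertonic-saline infusion.

    The stimulus onset is ``pump_on`` plus the measured infusion-line lag
    (5 min). Basal rate is the mean over the 5 min before onset (10 min for
    phasic cells). The 30-s-binned rate series is expressed as change from
    basal; the headline response is the mean rate 20–30 min after onset
    minus basal; the slope is a least-squares fit through the origin of the
    mean change (in 5-min bins) against mmol infused at bin midpoints.
    """
    cfg = cfg or AnalysisConfig()
    onset = pump_on + cfg.pump_lag * 60.0
    basal_span = (
        cfg.osmotic_basal_window_phasic if phasic else cfg.osmotic_basal_window_cont
    ) * 60.0
    if pump_on < 600.0 or onset - basal_span < 0:
        raise InsufficientDataError(
            "need >=10 min of basal record before the pump switches on"
        )
    lo, hi = (m * 60.0 for m in cfg.osmotic_response_window)
    if onset + hi > train.duration:
        raise InsufficientDataError("record ends before the osmotic response window")
    basal = mean_rate(train, (onset - basal_span, onset))
    series = bin_rate(train, 30.0, start=onset, end=onset + infusion_duration_min * 60.0)
    series = RateSeries(series.bin_width, series.start, series.values - basal)
    response = mean_rate(train, (onset + lo, onset + hi)) - basal

    # slope through origin: mean change in 5-min bins vs mmol at midpoints
    five = bin_rate(train, 300.0, start=onset, end=onset + infusion_duration_min * 60.0)
    change = five.values - basal
    mid_min = (five.bin_centres - onset) / 60.0
    mmol = np.asarray(infused_mmol_at(mid_min))
    slope = float(np.sum(mmol * change) / np.sum(mmol**2)) if mmol.size else np.nan
    return OsmoticResponse(
        series=series,
        basal_rate=basal,
        response_20_30=response,
        slope_per_mmol=slope,
        onset=onset,
    )


def psth(
    train: SpikeTrain,
    stim_times: np.ndarray,
    cfg: AnalysisConfig | None = None,
    pre_window: float = 1.0,
    post_window: float = 2.0,
) -> PSTH:
    """Peristimulus-time histogram in 40-ms bins, as a percentage of the
    mean pre-stimulation count per bin.

    Counts are accumulated over ``post_window`` seconds after each of >=10
    stimuli and referenced to the mean count per 40-ms bin in the
    ``pre_window`` seconds before each stimulus.
    """
    cfg = cfg or AnalysisConfig()
    stim = np.asarray(stim_times, dtype=float)
    if stim.size < 10:
        raise InsufficientDataError("PSTH needs at least 10 stimuli")
    w = cfg.psth_bin / 1000.0
    n_bins = int(round(post_window / w))
    counts = np.zeros(n_bins)
    pre_count = 0.0
    for s in stim:
        rel = train.times - s
        counts += np.histogram(rel, bins=np.arange(n_bins + 1) * w)[0]
        pre_count += np.sum((rel >= -pre_window) & (rel < 0))
    pre_per_bin = pre_count / stim.size / (pre_window / w)
    if pre_per_bin == 0:
        raise InsufficientDataError("zero pre-stimulation count: PSTH undefined")
    values = 100.0 * (counts / stim.size) / pre_per_bin
    return PSTH(bin_width=cfg.psth_bin, values=values, n_stimuli=int(stim.size))
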