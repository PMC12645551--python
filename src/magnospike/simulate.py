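"""Synthetic spike trains, experiments and voltage traces.

The spike generator is a discrete-time renewal model of a magnocellular
neurone: synaptic input arrives randomly at ``input_rate`` while the
probability of spiking is modulated by post-spike afterpotentials — a
hyperpolarizing afterpotential (HAP, amplitude H, time constant tau_H)
that suppresses firing immediately after a spike and a depolarizing
afterpotential (DAP, amplitude D, time constant tau_D) that transiently
raises excitability on a slower time scale. At elapsed time ``dt`` since
the last spike the firing intensity is

    lambda(dt) = input_rate * exp(-H * e^(-dt/tau_H) + D * e^(-dt/tau_D))

(zero within an absolute refractory period), and in each 0.1-ms time step
a spike occurs with probability ``1 - exp(-lambda * step)``. With
H = D = 0 the model reduces to a homogeneous Poisson process (ISI CV = 1);
H > 0 imposes relative refractoriness (CV < 1, positive ISI mode); D > 0
produces a hazard peak above the asymptote.

Stationary trains are sampled exactly by inversion of the per-step ISI law
(identical in distribution to naive stepping, vectorised over intervals);
time-varying experiments use Ogata thinning against the envelope
``max(rate) * e^D``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

from .core import (
    EventLabel,
    EventMarker,
    RecordingMeta,
    SpikeTrain,
    ValidationError,
)
from .responses import infused_mmol_at
from .waveforms import VoltageTrace

__all__ = [
    "RenewalModelParams",
    "PhasicModelParams",
    "PhasicTruth",
    "ExperimentEffect",
    "ExperimentScript",
    "WaveformTemplate",
    "simulate_postspike_renewal",
    "simulate_phasic",
    "simulate_experiment",
    "simulate_voltage",
    "analytic_mean_rate",
    "calibrate_input_rate",
]

_DT = 1e-4  # s, generator time step (0.1-ms deposit resolution)


@dataclass(frozen=True)
class RenewalModelParams:
    """Parameters of the post-spike renewal generator."""

    input_rate: float  # events/s
    hap_amp: float = 0.0  # H, dimensionless
    hap_tau: float = 20.0  # ms
    dap_amp: float = 0.0  # D, dimensionless
    dap_tau: float = 100.0  # ms
    refractory: float = 0.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_rate < 0:
            raise ValidationError("input_rate must be >= 0")
        if self.hap_tau <= 0 or self.dap_tau <= 0:
            raise ValidationError("time constants must be positive")
        if self.refractory < 0:
            raise ValidationError("refractory must be >= 0")

    def intensity(self, elapsed_ms: np.ndarray) -> np.ndarray:
        """lambda(elapsed) in events/s; zero within the refractory period."""
        e = np.asarray(elapsed_ms, dtype=float)
        lam = self.input_rate * np.exp(
            -self.hap_amp * np.exp(-e / self.hap_tau)
            + self.dap_amp * np.exp(-e / self.dap_tau)
        )
        return np.where(e < self.refractory, 0.0, lam)


def _hazard_grid(p: RenewalModelParams) -> tuple[np.ndarray, float]:
    """Cumulative hazard on the step grid, plus the asymptotic intensity.

    The grid covers the refractory period and ~10 afterpotential time
    constants; beyond it the intensity is treated as constant (the
    exponential terms are below 5e-5 of their amplitudes there).
    """
    span_ms = max(p.refractory + 10.0 * max(p.hap_tau, p.dap_tau), 100.0)
    k = np.arange(1, int(np.ceil(span_ms / (_DT * 1000.0))) + 1)
    lam = p.intensity(k * _DT * 1000.0)
    cumhaz = np.cumsum(lam * _DT)
    lam_inf = float(p.intensity(np.array([span_ms + 1.0]))[0])
    return cumhaz, lam_inf


def _sample_isis(p: RenewalModelParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n iid ISIs (seconds) of the discrete-time renewal model.

    Inversion: ISI = (k+1) steps where k is the first step at which the
    cumulative hazard exceeds a standard-exponential draw; beyond the
    tabulated grid the constant-intensity tail is sampled geometrically.
    """
    cumhaz, lam_inf = _hazard_grid(p)
    e = rng.exponential(size=n)
    k = np.searchsorted(cumhaz, e)  # 0-based index of the firing step - 1
    isis = (k + 1).astype(float) * _DT
    over = k >= cumhaz.size
    if np.any(over):
        if lam_inf <= 0:
            raise ValidationError("intensity vanishes: train would terminate")
        extra = np.ceil((e[over] - cumhaz[-1]) / (lam_inf * _DT))
        isis[over] = (cumhaz.size + extra) * _DT
    return isis


def analytic_mean_rate(p: RenewalModelParams) -> float:
    """Mean firing rate (spikes/s) of the renewal model, from the exact
    discrete-time survival function: E[ISI] = step * sum_k S_k."""
    cumhaz, lam_inf = _hazard_grid(p)
    surv = np.exp(-cumhaz)
    q = np.exp(-lam_inf * _DT)
    mean_isi = _DT * (1.0 + surv.sum() + surv[-1] * q / (1.0 - q))
    return 1.0 / mean_isi


def calibrate_input_rate(
    target_rate: float, template: RenewalModelParams
) -> RenewalModelParams:
    """Return a copy of ``template`` whose input_rate gives the requested
    mean output rate (root-found on the analytic renewal rate)."""
    if target_rate <= 0:
        raise ValidationError("target_rate must be positive")

    def f(r: float) -> float:
        return analytic_mean_rate(replace(template, input_rate=r)) - target_rate

    hi = target_rate * 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e7:
            raise ValidationError("cannot reach target rate")
    return replace(template, input_rate=brentq(f, 1e-9, hi, xtol=1e-10))


def simulate_postspike_renewal(
    p: RenewalModelParams, duration: float, rng: np.random.Generator | None = None
) -> SpikeTrain:
    """Stationary spike train of the renewal model over ``duration`` s.

    Reproducible for a fixed seed. The epoch t=0 is treated as a virtual
    spike, so the first interval is drawn from the same renewal law.
    """
    rng = rng or np.random.default_rng(p.seed)
    mean_isi = 1.0 / analytic_mean_rate(p)
    times: list[np.ndarray] = []
    t = 0.0
    while t < duration:
        batch = max(int((duration - t) / mean_isi * 1.1) + 50, 100)
        isis = _sample_isis(p, batch, rng)
        new = t + np.cumsum(isis)
        times.append(new)
        t = float(new[-1])
    all_times = np.concatenate(times)
    return SpikeTrain(all_times[all_times < duration], duration=duration)


# ---------------------------------------------------------------------------
# Phasic generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhasicModelParams:
    """Alternating burst/silence generator for phasic vasopressin cells.

    Defaults emulate the salt-loaded phenotype: ~79-s bursts, ~24-s
    silences, 8.1 spikes/s within bursts. Durations are truncated-normal;
    the truncation floor sits just above the segmentation criteria (6 s)
    and the underlying location is adjusted so the *truncated* mean equals
    the requested mean, keeping the generated conditions on target.
    """

    burst_duration_mean: float = 79.0  # s
    burst_duration_sd: float = 53.0
    silence_duration_mean: float = 24.0  # s
    silence_duration_sd: float = 15.0
    intraburst_rate: float = 8.1  # spikes/s, mean rate within bursts
    intraburst: RenewalModelParams = field(
        default_factory=lambda: RenewalModelParams(input_rate=1.0, hap_amp=3.0,
                                                   hap_tau=25.0)
    )
    duration_floor: float = 6.0  # s, truncation bound for both states
    seed: int = 0


@dataclass
class PhasicTruth:
    """Realized generator state, for parameter-recovery checks."""

    bursts: list[tuple[float, float]] = field(default_factory=list)
    silences: list[tuple[float, float]] = field(default_factory=list)

    @property
    def mean_burst_duration(self) -> float:
        return float(np.mean([b - a for a, b in self.bursts]))

    @property
    def mean_silence_duration(self) -> float:
        return float(np.mean([b - a for a, b in self.silences]))


def _truncnorm_location(target_mean: float, sd: float, floor: float) -> float:
    """Location mu such that a normal(mu, sd) truncated below at ``floor``
    has mean ``target_mean``."""
    if sd <= 0:
        return target_mean

    def trunc_mean(mu: float) -> float:
        a = (floor - mu) / sd
        phi = np.exp(-0.5 * a * a) / np.sqrt(2.0 * np.pi)
        return mu + sd * phi / ndtr(-a)

    lo, hi = target_mean - 10.0 * sd, target_mean + sd
    return brentq(lambda m: trunc_mean(m) - target_mean, lo, hi, xtol=1e-9)


def _draw_truncnorm(
    rng: np.random.Generator, mu: float, sd: float, floor: float
) -> float:
    if sd <= 0:
        return max(mu, floor)
    while True:
        x = rng.normal(mu, sd)
        if x >= floor:
            return float(x)


def simulate_phasic(
    p: PhasicModelParams,
    duration: float,
    return_truth: bool = False,
) -> SpikeTrain | tuple[SpikeTrain, PhasicTruth]:
    """Alternating burst/silence train; spikes within bursts follow the
    intraburst renewal model calibrated to ``intraburst_rate``."""
    rng = np.random.default_rng(p.seed)
    intraburst = calibrate_input_rate(p.intraburst_rate, p.intraburst)
    mu_b = _truncnorm_location(p.burst_duration_mean, p.burst_duration_sd,
                               p.duration_floor)
    mu_s = _truncnorm_location(p.silence_duration_mean, p.silence_duration_sd,
                               p.duration_floor)
    truth = PhasicTruth()
    times: list[np.ndarray] = []
    t = _draw_truncnorm(rng, mu_s, p.silence_duration_sd, p.duration_floor) / 2.0
    truth.silences.append((0.0, t))
    while t < duration:
        b = _draw_truncnorm(rng, mu_b, p.burst_duration_sd, p.duration_floor)
        burst_end = min(t + b, duration)
        n_exp = int(p.intraburst_rate * b * 1.5) + 50
        isis = _sample_isis(intraburst, n_exp, rng)
        spikes = t + np.cumsum(isis)
        while spikes.size and spikes[-1] < burst_end:  # pragma: no cover
            more = spikes[-1] + np.cumsum(_sample_isis(intraburst, 50, rng))
            spikes = np.concatenate([spikes, more])
        spikes = spikes[spikes < burst_end]
        times.append(spikes)
        truth.bursts.append((t, t + b))
        s = _draw_truncnorm(rng, mu_s, p.silence_duration_sd, p.duration_floor)
        truth.silences.append((t + b, t + b + s))
        t = t + b + s
    all_times = np.concatenate(times) if times else np.zeros(0)
    train = SpikeTrain(all_times[all_times < duration], duration=duration)
    return (train, truth) if return_truth else train


# ---------------------------------------------------------------------------
# Scripted experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExperimentEffect:
    """One rate-modulation event.

    kinds
    -----
    ``step``
        Additive change of ``delta`` spikes/s over ``[time, time+duration]``.
    ``transient``
        CCK-like alpha-profile change peaking at ``delta`` spikes/s at
        ``peak_s`` after onset and decaying to <2% of peak by ~5 peak
        times (defaults: peak 2.5 min, resolved by ~15 min).
    ``ramp``
        Hypertonic-infusion ramp: additive ``slope_per_mmol`` x mmol(t)
        with mmol following the 2 M x 26 uL/min schedule, starting
        ``lag_s`` after ``time`` (pump lag) and held constant after
        ``duration`` s of infusion.
    """

    label: EventLabel
    time: float  # s
    kind: str = "step"
    delta: float = 0.0  # spikes/s (peak, for transients)
    duration: float = 300.0  # s
    peak_s: float = 150.0  # transient time-to-peak
    slope_per_mmol: float = 0.0
    lag_s: float = 300.0

    def rate_delta(self, t: np.ndarray) -> np.ndarray:
        rel = np.asarray(t, dtype=float) - self.time
        if self.kind == "step":
            return np.where((rel >= 0) & (rel < self.duration), self.delta, 0.0)
        if self.kind == "transient":
            x = np.maximum(rel, 0.0) / self.peak_s
            return np.where(rel >= 0, self.delta * x * np.exp(1.0 - x), 0.0)
        if self.kind == "ramp":
            infused = np.clip(rel - self.lag_s, 0.0, self.duration) / 60.0
            return self.slope_per_mmol * np.asarray(infused_mmol_at(infused))
        raise ValidationError(f"unknown effect kind {self.kind!r}")


@dataclass
class ExperimentScript:
    effects: list[ExperimentEffect] = field(default_factory=list)

    def rate_delta(self, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(t, dtype=float))
        for eff in self.effects:
            out = out + eff.rate_delta(t)
        return out

    def events(self) -> list[EventMarker]:
        return [EventMarker(eff.label, eff.time) for eff in self.effects]


def simulate_experiment(
    base: RenewalModelParams,
    script: ExperimentScript,
    duration: float,
    meta: RecordingMeta | None = None,
) -> tuple[SpikeTrain, RecordingMeta]:
    """Spike train under a scripted time-varying stimulus.

    The scripted rate change is applied as a multiplier on the input rate,
    scaled so that the programmed delta is expressed in output spikes/s
    (exact for a Poisson base; approximate under strong afterpotentials).
    Sampling is by Ogata thinning against the envelope
    ``max(rate) * e^dap_amp``; exact for the continuous-time intensity.
    """
    r0 = analytic_mean_rate(base)
    grid = np.arange(0.0, duration, 1.0)
    mult = (r0 + script.rate_delta(grid)) / r0
    if np.any(mult < 0):
        raise ValidationError("scripted rate goes negative")
    rng = np.random.default_rng(base.seed)
    lam_max = base.input_rate * float(mult.max()) * np.exp(max(base.dap_amp, 0.0))
    times: list[float] = []
    t_last = -np.inf
    t = 0.0
    # pre-draw candidate increments in blocks
    while t < duration:
        incs = rng.exponential(1.0 / lam_max, size=4096)
        us = rng.random(4096)
        for dt_c, u in zip(incs, us):
            t += dt_c
            if t >= duration:
                break
            elapsed_ms = (t - t_last) * 1000.0
            g = float(base.intensity(np.array([elapsed_ms]))[0]) / max(
                base.input_rate, 1e-300
            )
            m = mult[min(int(t), mult.size - 1)]
            if u * lam_max < base.input_rate * m * g:
                times.append(t)
                t_last = t
    meta = meta or RecordingMeta()
    meta.events = script.events()
    return SpikeTrain(np.asarray(times), duration=duration), meta


# ---------------------------------------------------------------------------
# Voltage synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveformTemplate:
    """Extracellular spike template, recorded (negative-going) polarity.

    The shape is a negative gaussian spike followed by a post-spike
    hyperpolarization decaying with ``hap_tau_ms`` (30–80 ms observed) and
    an optional depolarizing hump with ``dap_tau_ms``.
    """

    spike_amp: float = 1.0  # mV, magnitude of the negative deflection
    spike_width_ms: float = 0.4
    hap_amp: float = 0.15
    hap_tau_ms: float = 40.0
    dap_amp: float = 0.0
    dap_tau_ms: float = 120.0
    span_ms: float = 400.0

    def render(self, sampling_rate: float = 10_000.0) -> np.ndarray:
        """Sample the template on ``[0, span_ms)``; index 0 is the trigger."""
        t = np.arange(0.0, self.span_ms, 1000.0 / sampling_rate)
        spike = -self.spike_amp * np.exp(-0.5 * (t / self.spike_width_ms) ** 2)
        onset = 1.0 - np.exp(-t / (2.0 * self.spike_width_ms))
        # intracellular hyperpolarization appears as a positive deflection
        # in the (inverted) extracellular record
        after = (
            self.hap_amp * np.exp(-t / self.hap_tau_ms)
            - self.dap_amp * np.exp(-t / self.dap_tau_ms)
        ) * onset
        return spike + after * self.spike_amp


def simulate_voltage(
    train: SpikeTrain,
    template: WaveformTemplate | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    sampling_rate: float = 10_000.0,
) -> VoltageTrace:
    """Overlap-add of the template at each spike time plus gaussian noise."""
    template = template or WaveformTemplate()
    rng = np.random.default_rng(seed)
    n = int(np.ceil(train.duration * sampling_rate)) + 1
    shape = template.render(sampling_rate)
    v = rng.normal(0.0, noise_sd, size=n + shape.size) if noise_sd > 0 else np.zeros(
        n + shape.size
    )
    idx = np.round(train.times * sampling_rate).astype(int)
    for i in idx:
        v[i : i + shape.size] += shape
    return VoltageTrace(samples=v[:n], sampling_rate=sampling_rate)
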