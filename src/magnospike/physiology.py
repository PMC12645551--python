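"""Physiological back-of-envelope arithmetic for hypertonic infusion and
hormone secretion.

All operations are pure and linear in their stated regime. Two
sodium-per-mmol constants circulate for the same conversion — an
empirical 6.1 mM/mmol from direct plasma measurements and a ~4.9 mM/mmol
figure quoted alongside (equivalently 9.8 mOsm/kg per mmol); they are
inconsistent with each other, so the caller must name which one to use.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .core import ValidationError

__all__ = [
    "InfusionSpec",
    "OsmoConstants",
    "NaMode",
    "infused_mmol",
    "predicted_na_rise",
    "expected_rate_elevation",
    "secretion_arithmetic",
    "rate_to_plasma_vp",
]


@dataclass(frozen=True)
class InfusionSpec:
    concentration: float = 2.0  # mol/L
    rate: float = 26.0  # uL/min
    duration: float = 30.0  # min

    def __post_init__(self) -> None:
        if min(self.concentration, self.rate, self.duration) <= 0:
            raise ValidationError("infusion parameters must be positive")


@dataclass(frozen=True)
class OsmoConstants:
    tbw_fraction: float = 0.7  # L/kg total body water (245 mL per 350 g)
    na_per_mmol_empirical: float = 6.1  # mM plasma [Na+] per mmol infused
    mosm_per_mmol: float = 9.8  # mOsm/kg per mmol (~4.9 mM Na+ per mmol)
    rate_sensitivity: float = 0.2  # spikes/s per mOsm/kg
    plasma_vp_per_spike: float = 6.4  # pg/mL per spikes/s


class NaMode(str, enum.Enum):
    """Which Na-rise constant to apply: the theoretical body-water
    dilution or the empirically measured 6.1 mM/mmol."""

    THEORETICAL = "theoretical"
    EMPIRICAL = "empirical"


def infused_mmol(spec: InfusionSpec, elapsed_min: float | None = None) -> float:
    """mmol NaCl delivered after ``elapsed_min`` minutes (default: the full
    infusion). 2 M x 26 uL/min x 30 min = 1.56 mmol."""
    if elapsed_min is None:
        elapsed_min = spec.duration
    if elapsed_min < 0 or elapsed_min > spec.duration:
        raise ValidationError("elapsed time must lie within the infusion")
    return spec.concentration * spec.rate * 1e-3 * elapsed_min


def predicted_na_rise(
    mmol: float,
    mode: NaMode | str,
    body_mass_g: float = 350.0,
    constants: OsmoConstants = OsmoConstants(),
) -> tuple[float, float]:
    """Steady-state rise in plasma [Na+] (mM) and osmolality (mOsm/kg)
    after retaining ``mmol`` of NaCl.

    ``theoretical`` distributes the load over total body water
    (mmol / (mass x 0.7 L/kg)); ``empirical`` applies the measured
    6.1 mM/mmol. Osmolality rises by twice the [Na+] rise (the anion
    contributes equally).
    """
    if body_mass_g <= 0:
        raise ValidationError("body mass must be positive")
    mode = NaMode(mode)
    if mode is NaMode.THEORETICAL:
        tbw_l = body_mass_g / 1000.0 * constants.tbw_fraction
        d_na = mmol / tbw_l
    else:
        d_na = mmol * constants.na_per_mmol_empirical
    return d_na, 2.0 * d_na


def expected_rate_elevation(
    delta_osm: float, constants: OsmoConstants = OsmoConstants()
) -> float:
    """Firing-rate elevation expected from an osmolality rise, at the
    euhydrated sensitivity of 0.2 spikes/s per mOsm/kg (39 mOsm/kg -> 7.8
    spikes/s)."""
    return constants.rate_sensitivity * delta_osm


def secretion_arithmetic(
    rate_ng_per_h: float, pituitary_content_ng: float
) -> tuple[float, int]:
    """Daily secretion (ng/day) implied by an hourly rate, and the integer
    percentage of pituitary content it represents (half-away-from-zero
    rounding: 14 ng/h against 875 ng -> 336 ng/day, 38%)."""
    if pituitary_content_ng <= 0:
        raise ValidationError("pituitary content must be positive")
    daily = rate_ng_per_h * 24.0
    pct = 100.0 * daily / pituitary_content_ng
    # round half away from zero, matching the printed integer percentages
    pct_int = int(pct + 0.5) if pct >= 0 else -int(-pct + 0.5)
    return daily, pct_int


def rate_to_plasma_vp(
    delta_rate: float, constants: OsmoConstants = OsmoConstants()
) -> float:
    """Predicted rise in plasma vasopressin (pg/mL) for a rise in
    population firing rate, 6.4 pg/mL per spikes/s; the linear regime
    extends to ~6 spikes/s and a warning is issued beyond it."""
    if abs(delta_rate) > 6:
        warnings.warn(
            "rate change outside the 1-6 spikes/s linear regime",
            stacklevel=2,
        )
    return constants.plasma_vp_per_spike * delta_rate
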