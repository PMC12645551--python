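"""Literature meta-aggregation of salt-loading studies.

Packaged TSV transcriptions of four published-literature tables (plasma
osmolality, haematocrit, pituitary hormone content as % of control, and
plasma hormone concentration) are aggregated with the original rules:
one value per study (per-study averaging with a day filter that depends
on the variable), then the mean of study means with sample SD, SEM and a
normal-approximation 95% CI (z = 1.96).

Fixture rows are tagged ``obs`` (printed observations), ``printed_av``
(the source's own per-study average column) or ``printed_delta``. Headline
aggregates use the printed per-study averages where the source prints
them; :func:`per_study_average` recomputes them from observations by rule.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InsufficientDataError, ValidationError

__all__ = [
    "MetaSummary",
    "load_table",
    "per_study_average",
    "summarize",
    "paired_deltas",
    "day_trend",
    "TABLE_FILES",
]

Z95 = 1.96

TABLE_FILES = {
    4: "table4_osmolality.tsv",
    5: "table5_haematocrit.tsv",
    6: "table6_pituitary.tsv",
    7: "table7_plasma.tsv",
}

#: day filter applied when recomputing a per-study average from observations
RULES = {
    "plasma": lambda day: day > 2,
    "pituitary": lambda day: (day >= 5) & (day <= 8),
    "haematocrit": lambda day: np.full_like(day, True, dtype=bool),
    "day7": lambda day: day == 7,
}


@dataclass
class MetaSummary:
    n: int
    mean: float
    sd: float | None  # sample SD; None for n < 2
    sem: float | None
    ci_low: float | None
    ci_high: float | None


def load_table(table: int) -> pd.DataFrame:
    """Load a packaged table transcription as a DataFrame.

    Columns: study_id, variable, group (EU/SL), day (nullable Int64),
    value (float), kind (obs | printed_av | printed_delta).
    """
    if table not in TABLE_FILES:
        raise ValidationError(f"no packaged table {table}; have {sorted(TABLE_FILES)}")
    ref = importlib.resources.files("magnospike.tables") / TABLE_FILES[table]
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"study_id": str, "kind": str})
    df["day"] = df["day"].astype("Int64")
    df["value"] = df["value"].astype(float)
    return df


def per_study_average(records: pd.DataFrame, rule: str) -> float:
    """Single value for one study from its SL observations under a day rule.

    Rules: ``plasma`` keeps days > 2; ``pituitary`` keeps days 5–8;
    ``haematocrit`` keeps all SL observations; ``day7`` keeps day 7 only.
    Raises if no observation qualifies (caller excludes the study).
    """
    if rule not in RULES:
        raise ValidationError(f"unknown rule {rule!r}; have {sorted(RULES)}")
    obs = records[(records["kind"] == "obs") & (records["group"] == "SL")]
    if obs.empty:
        raise InsufficientDataError("study has no salt-loaded observations")
    day = obs["day"].to_numpy(dtype=float)
    keep = RULES[rule](day)
    if not np.any(keep):
        raise InsufficientDataError("no observation passes the day rule")
    return float(obs["value"].to_numpy()[keep].mean())


def summarize(values: np.ndarray) -> MetaSummary:
    """Mean of study means with sample SD, SEM and z-based 95% CI."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("no study values to summarize")
    mean = float(x.mean())
    if x.size < 2:
        return MetaSummary(n=1, mean=mean, sd=None, sem=None,
                           ci_low=None, ci_high=None)
    sd = float(np.std(x, ddof=1))
    sem = sd / np.sqrt(x.size)
    return MetaSummary(
        n=int(x.size),
        mean=mean,
        sd=sd,
        sem=sem,
        ci_low=mean - Z95 * sem,
        ci_high=mean + Z95 * sem,
    )


def paired_deltas(
    eu: dict[str, float], sl: dict[str, float]
) -> tuple[dict[str, float], MetaSummary]:
    """Per-study (SL − EU) differences over the studies present in both
    mappings, with their summary. Unmatched studies are excluded."""
    matched = sorted(set(eu) & set(sl))
    if not matched:
        raise InsufficientDataError("no matched study pairs")
    deltas = {s: sl[s] - eu[s] for s in matched}
    return deltas, summarize(np.array(list(deltas.values())))


def day_trend(days: np.ndarray, deltas: np.ndarray) -> float:
    """Least-squares slope through the origin of delta against day."""
    d = np.asarray(days, dtype=float)
    y = np.asarray(deltas, dtype=float)
    if d.size == 0 or np.all(d == 0):
        raise ValidationError("day trend needs non-zero day labels")
    return float(np.sum(d * y) / np.sum(d * d))


# ---------------------------------------------------------------------------
# Headline aggregates
# ---------------------------------------------------------------------------

def eu_values(df: pd.DataFrame, variable: str) -> dict[str, float]:
    sel = df[(df["kind"] == "obs") & (df["group"] == "EU")
             & (df["variable"] == variable)]
    return dict(zip(sel["study_id"], sel["value"]))


def printed_study_averages(df: pd.DataFrame, variable: str) -> dict[str, float]:
    sel = df[(df["kind"] == "printed_av") & (df["variable"] == variable)]
    return dict(zip(sel["study_id"], sel["value"]))


def printed_deltas(df: pd.DataFrame, variable: str) -> dict[str, float]:
    sel = df[(df["kind"] == "printed_delta") & (df["variable"] == variable)]
    return dict(zip(sel["study_id"], sel["value"]))


def recomputed_study_averages(
    df: pd.DataFrame, variable: str, rule: str
) -> dict[str, float]:
    """Per-study averages recomputed from observations by the day rule;
    studies with no qualifying observation are silently excluded."""
    out: dict[str, float] = {}
    sub = df[df["variable"] == variable]
    for study, records in sub.groupby("study_id"):
        try:
            out[study] = per_study_average(records, rule)
        except InsufficientDataError:
            continue
    return out


def osmolality_headline() -> dict[str, MetaSummary]:
    """Aggregates of the osmolality table: euhydrated baseline, day-7
    level and the printed day-7 minus euhydrated per-study deltas."""
    df = load_table(4)
    eu = np.array(list(eu_values(df, "osmolality").values()))
    d7 = np.array(list(
        recomputed_study_averages(df, "osmolality", "day7").values()
    ))
    deltas = np.array(list(printed_deltas(df, "osmolality_delta").values()))
    return {
        "euhydrated": summarize(eu),
        "day7": summarize(d7),
        "delta": summarize(deltas),
    }


def plasma_headline() -> dict[str, MetaSummary]:
    """Aggregates of the plasma-hormone table: euhydrated means, the
    printed salt-loaded per-study averages and their matched deltas."""
    df = load_table(7)
    out: dict[str, MetaSummary] = {}
    for hormone in ("plasma_VP", "plasma_OT"):
        eu = eu_values(df, hormone)
        sl = printed_study_averages(df, hormone)
        out[f"{hormone}_eu"] = summarize(np.array(list(eu.values())))
        out[f"{hormone}_sl"] = summarize(np.array(list(sl.values())))
        _, out[f"{hormone}_delta"] = paired_deltas(eu, sl)
    return out
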