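"""Interspike-interval distribution statistics.

CV, 1-ms histograms, mode with a clear-peak threshold, bias-corrected
(spreadsheet-convention) skewness and excess kurtosis, and across-cell
averaging of normalized distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import InsufficientDataError, ValidationError

__all__ = [
    "ISIDistribution",
    "ISIStats",
    "isi_cv",
    "isi_histogram",
    "isi_mode",
    "isi_skew_kurt",
    "isi_stats",
    "population_mean_distribution",
]


@dataclass
class ISIDistribution:
    """Histogram of ISIs over half-open bins ``[k*w, (k+1)*w)`` ms."""

    bin_width: float  # ms
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def normalized(self) -> np.ndarray:
        """Per-bin fraction of all intervals; sums to 1 when total > 0."""
        n = self.total
        return self.counts / n if n else self.counts.astype(float)

    @property
    def bin_centres(self) -> np.ndarray:
        return (np.arange(self.counts.size) + 0.5) * self.bin_width


@dataclass
class ISIStats:
    cv: float
    mode: float | None  # ms, bin centre of the 1-ms histogram; None if no clear peak
    skewness: float
    kurtosis: float  # excess
    n_isis: int
    mean_isi: float = field(default=float("nan"))  # ms


def isi_cv(isis_ms: np.ndarray) -> float:
    """Coefficient of variation of ISIs: sample SD (n-1) divided by mean.

    1 for a purely random (Poisson) process, <1 for regular firing, >1 for
    clustered/phasic firing.
    """
    x = np.asarray(isis_ms, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("CV needs at least 2 ISIs")
    return float(np.std(x, ddof=1) / np.mean(x))


def isi_histogram(isis_ms: np.ndarray, bin_width: float = 1.0) -> ISIDistribution:
    """Count ISIs in half-open bins of ``bin_width`` ms from zero."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    x = np.asarray(isis_ms, dtype=float)
    if x.size == 0:
        return ISIDistribution(bin_width, np.zeros(0, dtype=int))
    n_bins = int(np.floor(x.max() / bin_width)) + 1
    counts, _ = np.histogram(x, bins=np.arange(n_bins + 1) * bin_width)
    return ISIDistribution(bin_width, counts)


def isi_mode(dist: ISIDistribution, min_peak_count: int = 5) -> float | None:
    """Centre of the maximal-count bin, or None when no bin reaches
    ``min_peak_count`` (cells firing too slowly to register a clear mode).

    Ties are broken toward the smallest interval.
    """
    if dist.counts.size == 0:
        return None
    peak = int(np.argmax(dist.counts))  # argmax takes the first maximum
    if dist.counts[peak] < min_peak_count:
        return None
    return float((peak + 0.5) * dist.bin_width)


def isi_skew_kurt(isis_ms: np.ndarray) -> tuple[float, float]:
    """Bias-corrected sample skewness and excess kurtosis.

    These are the spreadsheet SKEW/KURT conventions:

    ``skew = n/((n-1)(n-2)) * sum(z^3)``
    ``kurt = n(n+1)/((n-1)(n-2)(n-3)) * sum(z^4) - 3(n-1)^2/((n-2)(n-3))``

    with ``z = (x - mean)/s`` and ``s`` the sample (n-1) SD.
    """
    x = np.asarray(isis_ms, dtype=float)
    n = x.size
    if n < 4:
        raise InsufficientDataError("skew/kurtosis need at least 4 ISIs")
    s = np.std(x, ddof=1)
    if s == 0:
        raise InsufficientDataError("zero-variance ISIs: skew/kurtosis undefined")
    z = (x - x.mean()) / s
    skew = n / ((n - 1) * (n - 2)) * np.sum(z**3)
    kurt = (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * np.sum(z**4)
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )
    return float(skew), float(kurt)


def isi_stats(
    isis_ms: np.ndarray,
    mode_bin: float = 1.0,
    min_peak_count: int = 5,
) -> ISIStats:
    """Convenience bundle: CV, mode, skewness, kurtosis for one cell."""
    x = np.asarray(isis_ms, dtype=float)
    skew, kurt = isi_skew_kurt(x)
    return ISIStats(
        cv=isi_cv(x),
        mode=isi_mode(isi_histogram(x, mode_bin), min_peak_count),
        skewness=skew,
        kurtosis=kurt,
        n_isis=int(x.size),
        mean_isi=float(np.mean(x)),
    )


def population_mean_distribution(
    dists: list[ISIDistribution],
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted per-bin mean and SD of normalized distributions across cells.

    Distributions must share a bin width; shorter ones are zero-padded to
    the longest. Returns ``(mean, sd)`` arrays; SD is 0 for a single cell.
    """
    if not dists:
        raise InsufficientDataError("no distributions to average")
    w = dists[0].bin_width
    if any(d.bin_width != w for d in dists):
        raise ValidationError("mixed bin widths")
    length = max(d.counts.size for d in dists)
    mat = np.zeros((len(dists), length))
    for i, d in enumerate(dists):
        mat[i, : d.counts.size] = d.normalized
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0, ddof=1) if len(dists) > 1 else np.zeros(length)
    return mean, sd
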