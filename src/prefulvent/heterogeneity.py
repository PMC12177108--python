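"""Histogram-based ventilation-heterogeneity metrics.

All metrics operate on the sample of in-mask RVent values after trimming
extreme outliers (values strictly above the 99th percentile):

* IQD (interquartile distance): interquartile range divided by the mean —
  a dispersion index normalized to the overall ventilation level.
* IHI (inhomogeneity index): sum of absolute deviations from the median
  divided by the sum of values — borrowed from electrical impedance
  tomography ventilation analysis.
* Skewness and (non-excess) kurtosis of the distribution; kurtosis is 3 for
  a normal distribution.

Percentile convention everywhere: linear interpolation between closest
ranks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidParameterError, UndefinedMetricError

TRIM_PERCENTILE = 99.0
MIN_SAMPLE = 100


@dataclass
class HeterogeneityMetrics:
    iqd: float
    ihi: float
    skewness: float
    kurtosis: float  # non-excess: 3 for a normal distribution
    n_used: int
    trim_threshold: float


def trim_outliers(
    values: np.ndarray, percentile: float = TRIM_PERCENTILE
) -> tuple[np.ndarray, float]:
    """Drop values strictly above the given percentile (default 99th)."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < MIN_SAMPLE:
        raise InvalidParameterError(f"need >= {MIN_SAMPLE} values, got {values.size}")
    threshold = float(np.percentile(values, percentile))
    return values[values <= threshold], threshold


def compute_iqd(values: np.ndarray) -> float:
    """Interquartile range divided by the mean."""
    values = np.asarray(values, dtype=float).ravel()
    mean = values.mean()
    if mean <= 0:
        raise UndefinedMetricError("IQD undefined for non-positive mean")
    p25, p75 = np.percentile(values, [25.0, 75.0])
    return float((p75 - p25) / mean)


def compute_ihi(values: np.ndarray) -> float:
    """Sum of absolute deviations from the median over the sum of values."""
    values = np.asarray(values, dtype=float).ravel()
    total = values.sum()
    if total <= 0:
        raise UndefinedMetricError("IHI undefined for non-positive total")
    return float(np.abs(values - np.median(values)).sum() / total)


def compute_moments(values: np.ndarray) -> tuple[float, float]:
    """Standardized third moment and non-excess fourth moment."""
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 3:
        raise UndefinedMetricError("need at least 3 values")
    if values.std() <= 0:
        raise UndefinedMetricError("moments undefined for zero variance")
    return float(stats.skew(values)), float(stats.kurtosis(values, fisher=False))


def compute_heterogeneity(
    values: np.ndarray, trim_percentile: float = TRIM_PERCENTILE
) -> HeterogeneityMetrics:
    """Trim outliers, then compute all histogram heterogeneity metrics.

    A constant sample yields IQD = IHI = 0 with NaN moments (the standardized
    moments are undefined at zero variance).
    """
    trimmed, threshold = trim_outliers(values, trim_percentile)
    iqd = compute_iqd(trimmed)
    ihi = compute_ihi(trimmed)
    if trimmed.std() > 0:
        skewness, kurt = compute_moments(trimmed)
    else:
        skewness, kurt = float("nan"), float("nan")
    return HeterogeneityMetrics(iqd, ihi, skewness, kurt, trimmed.size, threshold)


def pooled_histogram(
    samples_by_group: Mapping[str, Sequence[np.ndarray]],
    n_bins: int = 50,
    upper: float | None = None,
) -> pd.DataFrame:
    """Pooled normalized ventilation histograms for cohort figures.

    Each subject's (trimmed) sample is rescaled by its own median, binned on
    a common grid, converted to a unit-area density, and the densities are
    averaged across subjects with equal weight. Returns a tidy table with
    columns ``group``, ``bin_left``, ``bin_center``, ``density``.
    """
    if not samples_by_group:
        raise InvalidParameterError("no groups supplied")
    rescaled: dict[str, list[np.ndarray]] = {}
    for group, samples in samples_by_group.items():
        if len(samples) == 0:
            raise InvalidParameterError(f"group {group!r} is empty")
        out = []
        for s in samples:
            s = np.asarray(s, dtype=float).ravel()
            med = np.median(s)
            if med <= 0:
                raise UndefinedMetricError("median rescaling needs a positive median")
            out.append(s / med)
        rescaled[group] = out
    if upper is None:
        upper = max(float(s.max()) for group in rescaled.values() for s in group)
    edges = np.linspace(0.0, upper, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for group, samples in rescaled.items():
        dens = np.mean(
            [np.histogram(s, bins=edges, density=True)[0] for s in samples], axis=0
        )
        rows.append(
            pd.DataFrame(
                {"group": group, "bin_left": edges[:-1], "bin_center": centers, "density": dens}
            )
        )
    return pd.concat(rows, ignore_index=True)
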