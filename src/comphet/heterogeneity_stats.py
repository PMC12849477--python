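"""Reference-anchored percentile-threshold shift statistics.

The same statistic serves flow cytometry (log10 fluorescence, thresholds
at the 75th/99th percentiles of an early reference timepoint) and
microscopy (per-image-normalized relative intensities, thresholds at the
95th/99th percentiles of the 0-h reference): fix thresholds from the
reference timepoint's distribution, compute per-timepoint exceedance
fractions, and report the change between a late timepoint and the
reference in percentage points (delta_pp).

Conventions, fixed once and reused repo-wide:

* percentiles use linear interpolation between order statistics
  (:func:`comphet._conventions.percentile`);
* "exceeding" a threshold means strictly greater than it (immaterial for
  continuous data, deterministic under ties);
* thresholds and fractions are always computed from the full measured
  population; display subsampling (:func:`subsample_for_display`) is for
  plots only and never feeds a statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._conventions import percentile

VALID_SCALES = ("log10_fluorescence", "relative_percent")


@dataclass
class SampleDistribution:
    """Single-cell values for one strain x timepoint sample."""

    strain: str
    timepoint_h: float
    values: np.ndarray
    scale: str = "log10_fluorescence"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.scale not in VALID_SCALES:
            raise ValueError(f"scale must be one of {VALID_SCALES}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.scale == "relative_percent" and self.values.size:
            if self.values.min() < 0 or self.values.max() > 100:
                raise ValueError("relative_percent values must lie in [0, 100]")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ThresholdSet:
    """Percentile thresholds anchored at a reference timepoint."""

    reference_timepoint: float
    quantile_levels: tuple[float, ...]
    thresholds: tuple[float, ...]

    def __post_init__(self):
        levels = np.asarray(self.quantile_levels, dtype=float)
        if not (np.all(np.diff(levels) > 0) and levels.min() > 0 and levels.max() < 100):
            raise ValueError("levels must be strictly increasing within (0, 100)")
        thr = np.asarray(self.thresholds, dtype=float)
        if np.any(np.diff(thr) < 0):
            raise ValueError("thresholds must be nondecreasing with level")
        self.quantile_levels = tuple(float(v) for v in levels)
        self.thresholds = tuple(float(v) for v in thr)


def log10_events(raw_values) -> tuple[np.ndarray, int]:
    """log10-transform linear fluorescence, dropping nonpositive values.

    Returns (log10 values, dropped count).  Dropping is reported, never
    silent; an all-nonpositive input is an error.
    """
    raw = np.asarray(raw_values, dtype=float).ravel()
    keep = raw > 0
    dropped = int(raw.size - keep.sum())
    if raw.size and not keep.any():
        raise ValueError("all values are nonpositive; nothing to log-transform")
    return np.log10(raw[keep]), dropped


def reference_thresholds(
    reference: SampleDistribution, levels: Iterable[float]
) -> ThresholdSet:
    """Thresholds at the given percentile levels of the reference sample.

    Computed from all measured values of the reference distribution,
    not from any display subsample.
    """
    if reference.n == 0:
        raise ValueError("empty reference distribution")
    if reference.n < 100:
        warnings.warn(
            f"reference has only {reference.n} values; thresholds are noisy",
            stacklevel=2,
        )
    levels = tuple(float(v) for v in levels)
    thr = tuple(float(percentile(reference.values, q)) for q in levels)
    return ThresholdSet(
        reference_timepoint=reference.timepoint_h,
        quantile_levels=levels,
        thresholds=thr,
    )


def exceedance_fraction(values, threshold: float) -> float:
    """Percent of values strictly greater than ``threshold``."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty sample")
    return 100.0 * float(np.count_nonzero(v > threshold)) / v.size


@dataclass
class ShiftReport:
    """Exceedance fractions and reference-to-late deltas per strain/level.

    ``fractions`` has one row per (strain, timepoint_h, level) with the
    exceedance percent and sample size; ``deltas`` one row per
    (strain, level) with delta_pp = fraction(late) - fraction(reference)
    in percentage points.
    """

    reference_timepoint: float
    late_timepoint: float
    levels: tuple[float, ...]
    thresholds: dict[str, ThresholdSet]
    fractions: pd.DataFrame
    deltas: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def delta_pp(self, strain: str, level: float) -> float:
        row = self.deltas[
            (self.deltas["strain"] == strain) & (self.deltas["level"] == level)
        ]
        if row.empty:
            raise KeyError(f"no delta for strain={strain!r}, level={level}")
        return float(row["delta_pp"].iloc[0])


def shift_report(
    samples: Iterable[SampleDistribution],
    reference_timepoint: float,
    late_timepoint: float,
    levels: Iterable[float] = (75.0, 99.0),
) -> ShiftReport:
    """Reference-anchored shift report across strains and timepoints.

    For each strain, thresholds are fixed from its own distribution at
    ``reference_timepoint``; exceedance fractions are computed for every
    provided timepoint and delta_pp contrasts ``late_timepoint`` against
    the reference.  All fractions come from the full samples.
    """
    levels = tuple(float(v) for v in levels)
    samples = list(samples)
    by_strain: dict[str, dict[float, SampleDistribution]] = {}
    for s in samples:
        by_strain.setdefault(s.strain, {})[s.timepoint_h] = s

    thr_sets: dict[str, ThresholdSet] = {}
    frac_rows = []
    delta_rows = []
    for strain, by_t in by_strain.items():
        for needed, name in (
            (reference_timepoint, "reference"),
            (late_timepoint, "late"),
        ):
            if needed not in by_t:
                raise ValueError(
                    f"strain {strain!r} is missing the {name} timepoint {needed} h"
                )
        ts = reference_thresholds(by_t[reference_timepoint], levels)
        thr_sets[strain] = ts
        fracs: dict[tuple[float, float], float] = {}
        for t, sample in sorted(by_t.items()):
            for level, threshold in zip(ts.quantile_levels, ts.thresholds):
                f = exceedance_fraction(sample.values, threshold)
                fracs[(t, level)] = f
                frac_rows.append(
                    {
                        "strain": strain,
                        "timepoint_h": t,
                        "level": level,
                        "fraction_pct": f,
                        "n": sample.n,
                    }
                )
        for level in levels:
            delta_rows.append(
                {
                    "strain": strain,
                    "level": level,
                    "delta_pp": fracs[(late_timepoint, level)]
                    - fracs[(reference_timepoint, level)],
                }
            )
    return ShiftReport(
        reference_timepoint=float(reference_timepoint),
        late_timepoint=float(late_timepoint),
        levels=levels,
        thresholds=thr_sets,
        fractions=pd.DataFrame(frac_rows),
        deltas=pd.DataFrame(delta_rows),
    )


def subsample_for_display(
    sample: SampleDistribution, n: int, seed: int
) -> SampleDistribution:
    """Seeded uniform subsample without replacement, for plotting only.

    If ``n`` exceeds the sample size the whole sample is returned with a
    warning.  Never use the result for thresholds or fractions.
    """
    if n >= sample.n:
        if n > sample.n:
            warnings.warn(
                f"requested {n} > sample size {sample.n}; returning all values",
                stacklevel=2,
            )
        values = sample.values.copy()
    else:
        rng = np.random.default_rng(seed)
        values = rng.choice(sample.values, size=n, replace=False)
    return SampleDistribution(
        strain=sample.strain,
        timepoint_h=sample.timepoint_h,
        values=values,
        scale=sample.scale,
    )


def distribution_summary(sample: SampleDistribution) -> dict:
    """Descriptive summary: n, median, IQR, moment-based skewness."""
    if sample.n < 3:
        raise ValueError("need >= 3 values for a distribution summary")
    v = sample.values
    q25, q75 = percentile(v, [25, 75])
    return {
        "n": sample.n,
        "median": float(np.median(v)),
        "iqr": float(q75 - q25),
        "skewness": float(sps.skew(v)),
    }
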