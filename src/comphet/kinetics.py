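"""Population-level competence kinetics.

Transformation frequency (TF) with detection-limit censoring, maximum
competence induction rate on the log10 scale, optical density at peak
transformability, MUG/Nile-Red reporter normalization, four-parameter
logistic (4PL) fitting, and steepest-slope ("peak") time extraction.

Transformation frequency is transformant CFU per total viable CFU.  A
measurement whose selective-plate count is indistinguishable from the
spontaneous-reversion background (no-DNA controls) is *censored*: it is
reported as "at or below the detection limit", never as zero, so that
log-scale analyses remain well defined.

The 4PL model used throughout is

    f(t) = a + (d - a) / (1 + (t / c)^(-b))

with lower asymptote ``a``, upper asymptote ``d``, inflection scale ``c``
(time units, c > 0) and hill slope ``b`` (dimensionless, b != 0).  With
``d > a`` and ``b > 0`` the curve increases from a to d and passes through
the midpoint at t = c.  For b > 1 the steepest slope occurs at the closed
form  t* = c * ((b - 1) / (b + 1))^(1/b);  for 0 < b <= 1 the derivative
is maximal at the lower end of the fit window, found numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_DETECTION_LIMIT = 1e-9  # spontaneous Trp+ reversion scale


# ---------------------------------------------------------------------------
# plate counts and transformation frequency
# ---------------------------------------------------------------------------


@dataclass
class PlateCount:
    """Colony counts from one transformation assay timepoint.

    ``selective_cfu`` counts transformant colonies (e.g. Trp+ on CAH
    agar); ``total_cfu`` counts total viable cells (e.g. on LB agar).
    Control counts come from the parallel no-DNA plating used to measure
    spontaneous reversion.
    """

    condition: str
    time_h: float
    selective_cfu: int
    total_cfu: int
    selective_dilution: float = 1.0
    total_dilution: float = 1.0
    control_selective_cfu: int | None = None
    control_total_cfu: int | None = None

    def __post_init__(self):
        if self.total_cfu <= 0:
            raise ValueError("total_cfu must be > 0 for a defined frequency")
        if self.selective_cfu < 0:
            raise ValueError("counts must be >= 0")
        if self.selective_dilution <= 0 or self.total_dilution <= 0:
            raise ValueError("dilution factors must be > 0")


@dataclass
class TFEntry:
    """Transformation frequency at one timepoint, possibly censored."""

    time_h: float
    tf: float
    censored: bool
    detection_limit: float
    condition: str = ""

    def __post_init__(self):
        if not (0.0 <= self.tf <= 1.0):
            raise ValueError("tf must lie in [0, 1]")
        if self.censored and self.tf != self.detection_limit:
            raise ValueError("censored entries carry the limit value")


@dataclass
class TFSeries:
    """Time course of transformation frequencies with provenance."""

    entries: list[TFEntry]
    detection_limit: float = DEFAULT_DETECTION_LIMIT

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time_h for e in self.entries])

    @property
    def tf(self) -> np.ndarray:
        return np.array([e.tf for e in self.entries])

    @property
    def censored(self) -> np.ndarray:
        return np.array([e.censored for e in self.entries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": [e.condition for e in self.entries],
                "time_h": self.times,
                "tf": self.tf,
                "censored": self.censored,
                "detection_limit": [e.detection_limit for e in self.entries],
            }
        )


def transformation_frequency(
    pc: PlateCount, default_detection_limit: float = DEFAULT_DETECTION_LIMIT
) -> TFEntry:
    """Transformation frequency from one plate count, with censoring.

    tf = (selective_cfu * selective_dilution) / (total_cfu * total_dilution).

    The detection limit is the reversion frequency measured on the no-DNA
    control plates when available (and above the default floor), else
    ``default_detection_limit``.  If the selective count does not exceed
    the background expected from spontaneous reversion, the entry is
    censored at the limit.
    """
    tf_raw = (pc.selective_cfu * pc.selective_dilution) / (
        pc.total_cfu * pc.total_dilution
    )
    reversion = 0.0
    if (
        pc.control_selective_cfu is not None
        and pc.control_total_cfu is not None
        and pc.control_total_cfu > 0
    ):
        reversion = (pc.control_selective_cfu * pc.selective_dilution) / (
            pc.control_total_cfu * pc.total_dilution
        )
    limit = max(reversion, default_detection_limit)
    # cells assayed on the selective plate, in selective-count units
    cells_on_selective = (pc.total_cfu * pc.total_dilution) / pc.selective_dilution
    expected_background = reversion * cells_on_selective
    if pc.selective_cfu <= expected_background or pc.selective_cfu == 0:
        return TFEntry(
            time_h=pc.time_h,
            tf=limit,
            censored=True,
            detection_limit=limit,
            condition=pc.condition,
        )
    return TFEntry(
        time_h=pc.time_h,
        tf=min(tf_raw, 1.0),
        censored=False,
        detection_limit=limit,
        condition=pc.condition,
    )


def tf_series(
    counts: list[PlateCount],
    default_detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> TFSeries:
    """Transformation-frequency time course from a list of plate counts."""
    entries = [transformation_frequency(pc, default_detection_limit) for pc in counts]
    entries.sort(key=lambda e: e.time_h)
    return TFSeries(entries=entries, detection_limit=default_detection_limit)


# ---------------------------------------------------------------------------
# induction rate and OD at peak
# ---------------------------------------------------------------------------


@dataclass
class InductionRate:
    """Maximum slope of log10-transformed TF, a competence induction rate."""

    max_log_slope: float  # log10 frequency per hour
    window: tuple[float, float]
    method: str = "sliding_ols"


def max_induction_rate(series: TFSeries, window_size: int = 3) -> InductionRate:
    """Maximum sliding-window least-squares slope of log10(TF) vs time.

    Censored entries never enter a fit window (a censored value is an
    upper bound, not a measurement).  Requires at least ``window_size``
    uncensored points.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    mask = ~series.censored
    t = series.times[mask]
    y = np.log10(series.tf[mask])
    if t.size < window_size:
        raise ValueError(
            f"need >= {window_size} uncensored points, have {t.size}"
        )
    best = -np.inf
    best_win = (t[0], t[-1])
    for i in range(t.size - window_size + 1):
        tw = t[i : i + window_size]
        yw = y[i : i + window_size]
        if tw[-1] == tw[0]:
            continue
        slope = np.polyfit(tw, yw, 1)[0]
        if slope > best:
            best = slope
            best_win = (float(tw[0]), float(tw[-1]))
    return InductionRate(max_log_slope=float(best), window=best_win)


def od_at_peak_tf(
    times: np.ndarray, od_values: np.ndarray, series: TFSeries
) -> tuple[float, float]:
    """OD at the timepoint of maximal (uncensored) transformation frequency.

    ``times``/``od_values`` must share the TF series' time grid.  Ties in
    the TF maximum resolve to the earliest time.  Returns (od, peak_time).
    """
    times = np.asarray(times, dtype=float)
    od_values = np.asarray(od_values, dtype=float)
    if times.shape != od_values.shape:
        raise ValueError("times and od_values must be congruent")
    mask = ~series.censored
    if not mask.any():
        raise ValueError("all TF entries are censored; no peak defined")
    tf = series.tf.copy()
    tf[~mask] = -np.inf
    peak_idx = int(np.argmax(tf))  # argmax takes the first of tied maxima
    peak_time = series.times[peak_idx]
    od_idx = np.nonzero(np.isclose(times, peak_time))[0]
    if od_idx.size == 0:
        raise ValueError(f"OD series has no value at peak time {peak_time}")
    return float(od_values[od_idx[0]]), float(peak_time)


# ---------------------------------------------------------------------------
# reporter normalization and 4PL fitting
# ---------------------------------------------------------------------------


def normalize_reporter(
    mug: np.ndarray, nilered: np.ndarray, floor: float = 0.0
) -> np.ndarray:
    """Pointwise MUG / Nile-Red ratio (promoter activity per biomass).

    Nile-Red values at or below ``floor`` are masked to NaN with a
    warning; if every point is masked the signal is unusable and an
    error is raised.
    """
    mug = np.asarray(mug, dtype=float)
    nilered = np.asarray(nilered, dtype=float)
    if mug.shape != nilered.shape:
        raise ValueError("mug and nilered series must share a time grid")
    bad = nilered <= floor
    if bad.all():
        raise ValueError("all Nile-Red values are at or below the floor")
    if bad.any():
        warnings.warn(
            f"masking {int(bad.sum())} point(s) with Nile-Red <= {floor}",
            stacklevel=2,
        )
    out = np.full_like(mug, np.nan)
    out[~bad] = mug[~bad] / nilered[~bad]
    return out


@dataclass
class FourPLParams:
    """Parameters of the four-parameter logistic f(t) = a + (d-a)/(1+(t/c)^-b)."""

    a: float  # lower asymptote
    d: float  # upper asymptote
    c: float  # inflection scale (time units)
    b: float  # hill slope

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("inflection scale c must be > 0")
        if self.b == 0:
            raise ValueError("hill slope b must be nonzero")


def fourpl(t, a: float, d: float, c: float, b: float):
    """Evaluate the 4PL curve; f(0) = a for b > 0 (d for b < 0)."""
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        u = np.power(t / c, b)
        frac = np.where(np.isinf(u), 1.0, u / (1.0 + u))
        frac = np.where(t == 0, 0.0 if b > 0 else 1.0, frac)
    return a + (d - a) * frac


def fourpl_derivative(t, a: float, d: float, c: float, b: float):
    """Analytic df/dt of the 4PL curve (0 at t = 0 for b > 1)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    with np.errstate(over="ignore"):
        u = np.power(t[pos] / c, b)
        val = (d - a) * b * u / (t[pos] * (1.0 + u) ** 2)
    out[pos] = np.where(np.isfinite(val), val, 0.0)
    return out


def fourpl_peak_time(params: FourPLParams, window: tuple[float, float]) -> float:
    """Time of steepest slope of the fitted 4PL within ``window``.

    Closed form t* = c ((b-1)/(b+1))^(1/b) for |b| > 1 (verified against
    numeric differentiation in the test suite); otherwise the argmax of
    |f'| on a dense grid over the window.
    """
    lo, hi = window
    b = params.b
    if abs(b) > 1:
        t_star = params.c * ((abs(b) - 1) / (abs(b) + 1)) ** (1 / abs(b))
        return float(np.clip(t_star, lo, hi))
    grid = np.linspace(max(lo, 1e-9), hi, 2001)
    deriv = np.abs(fourpl_derivative(grid, params.a, params.d, params.c, params.b))
    return float(grid[int(np.argmax(deriv))])


@dataclass
class FourPLFit:
    """A fitted 4PL curve with its derived slope metrics."""

    params: FourPLParams
    rss: float
    max_slope: float  # signal units per hour, derivative at peak_time
    peak_time: float  # hours, steepest slope of the fitted curve
    fit_window: tuple[float, float]
    degenerate: bool = False

    def predict(self, t):
        p = self.params
        return fourpl(t, p.a, p.d, p.c, p.b)


def fit_four_pl(
    times: np.ndarray,
    values: np.ndarray,
    fit_window: tuple[float, float] | None = None,
    max_nfev: int = 20000,
) -> FourPLFit:
    """Least-squares 4PL fit of a normalized reporter curve.

    The default fit window runs from the first timepoint to the time of
    the global maximum, excluding the post-plateau decline caused by
    substrate depletion.  Initialization is data-driven: a = min,
    d = max, c = mid-rise time, b from the endpoint trend sign.
    NaN values (e.g. masked normalization points) are dropped.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values) & np.isfinite(times)
    times, values = times[keep], values[keep]
    if times.size == 0:
        raise ValueError("no finite data to fit")
    if fit_window is None:
        # end at the global maximum (last occurrence, so flat data keeps
        # its full range) to exclude the substrate-depletion decline
        i_max = int(np.flatnonzero(values == values.max())[-1])
        fit_window = (float(times[0]), float(times[i_max]))
    lo, hi = fit_window
    mask = (times >= lo) & (times <= hi)
    t, y = times[mask], values[mask]
    if t.size < 5:
        raise ValueError(f"need >= 5 points in fit window, have {t.size}")

    a0, d0 = float(np.min(y)), float(np.max(y))
    span = d0 - a0
    if span <= 0 or not np.isfinite(span):
        # constant input: no rise to fit
        p = FourPLParams(a=a0, d=a0 + max(abs(a0), 1.0) * 1e-12, c=max(t[-1], 1.0), b=1.0)
        return FourPLFit(
            params=p,
            rss=float(np.sum((y - a0) ** 2)),
            max_slope=0.0,
            peak_time=float(t[0]),
            fit_window=fit_window,
            degenerate=True,
        )
    mid = a0 + span / 2
    above = np.nonzero(y >= mid)[0]
    c0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else max(
        float(np.median(t)), 1e-3
    )
    increasing = y[-1] >= y[0]
    b0 = 2.0 if increasing else -2.0

    def model(tt, a, d, c, b):
        return fourpl(tt, a, d, c, b)

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=[a0, d0, c0, b0],
            bounds=([-np.inf, -np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf, np.inf]),
            maxfev=max_nfev,
        )
    except RuntimeError as err:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"4PL fit failed to converge on window {fit_window} "
            f"(n={t.size}, init a={a0:.4g} d={d0:.4g} c={c0:.4g} b={b0}): {err}"
        ) from err
    a, d, c, b = (float(v) for v in popt)
    if b == 0:
        b = np.finfo(float).tiny
    params = FourPLParams(a=a, d=d, c=c, b=b)
    resid = y - fourpl(t, a, d, c, b)
    peak_time = fourpl_peak_time(params, (float(t[0]), float(t[-1])))
    max_slope = float(fourpl_derivative(np.array([peak_time]), a, d, c, b)[0])
    if d < a:
        warnings.warn("fitted curve is decreasing (d < a)", stacklevel=2)
    return FourPLFit(
        params=params,
        rss=float(np.sum(resid**2)),
        max_slope=max_slope,
        peak_time=peak_time,
        fit_window=fit_window,
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# density dependence of induction timing
# ---------------------------------------------------------------------------


def peak_time_vs_inoculum(
    fits: dict[float, "FourPLFit | float"],
) -> tuple[pd.DataFrame, float]:
    """Tabulate peak induction time against initial inoculation density.

    ``fits`` maps initial OD600 to either a :class:`FourPLFit` or a bare
    peak time.  Returns the table sorted by initial OD and the Spearman
    rank correlation between inoculum and peak time (the descriptive
    statistic for an inverse density/timing relation).  Identical peak
    times across conditions yield correlation 0 with a warning.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 conditions to relate peak time to inoculum")
    rows = []
    for od, fit in sorted(fits.items()):
        pt = fit.peak_time if isinstance(fit, FourPLFit) else float(fit)
        rows.append({"initial_od": float(od), "peak_time_h": pt})
    table = pd.DataFrame(rows)
    pts = table["peak_time_h"].to_numpy()
    if np.all(pts == pts[0]):
        warnings.warn("peak times identical across conditions", stacklevel=2)
        return table, 0.0
    rho = stats.spearmanr(table["initial_od"], table["peak_time_h"]).statistic
    return table, float(rho)
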