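"""Synthetic microscopy, flow-cytometry and kinetics data with ground truth.

The generator is phenomenological: it reproduces the *statistical
structure* of competence-reporter measurements in a coccoid bacterium,
not the gene-regulatory mechanism.  Single-cell fluorescence is a
two-component lognormal mixture — a baseline population plus an
"induced" high-expressing fraction — the minimal model for a unimodal,
right-skewed distribution whose upper tail grows as the induced fraction
rises over time.  Microscopy fields render cells as non-overlapping
disks (the organism is a coccus and samples are sonicated to disperse
aggregates before imaging) over an optionally tilted background, with
Poisson shot noise and Gaussian read noise.  Population kinetics follow
logistic growth, a log-logistic transformation-frequency trajectory with
Poisson plating noise and spontaneous-reversion background, and a 4PL
reporter curve with substrate-depletion decline.

All randomness flows from one scenario seed through per-stage
``numpy.random.SeedSequence`` spawns, so every stage is independently
reproducible and the derived seeds can be logged to a run manifest.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .containers import EventTable
from .image_quant import SegmentationResult
from .kinetics import FourPLParams, PlateCount, fourpl

# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


@dataclass
class MixtureModel:
    """Two-component lognormal intensity mixture on the log10 scale."""

    baseline_log_mean: float
    baseline_log_sd: float
    induced_log_mean: float
    induced_log_sd: float
    induced_fraction: float

    def __post_init__(self):
        if not (0.0 <= self.induced_fraction <= 1.0):
            raise ValueError("induced_fraction must lie in [0, 1]")
        if self.induced_log_mean <= self.baseline_log_mean:
            raise ValueError("induced_log_mean must exceed baseline_log_mean")
        if self.baseline_log_sd <= 0 or self.induced_log_sd <= 0:
            raise ValueError("log-sd values must be > 0")

    def with_fraction(self, p: float) -> "MixtureModel":
        return MixtureModel(
            self.baseline_log_mean,
            self.baseline_log_sd,
            self.induced_log_mean,
            self.induced_log_sd,
            p,
        )


@dataclass
class FieldGeometry:
    """Geometry of one rendered microscopy field."""

    width: int = 384
    height: int = 384
    cell_radius_mean: float = 6.0
    cell_radius_sd: float = 1.0
    n_cells: int = 50
    background_level: float = 200.0
    background_gradient: float = 0.0  # counts per pixel along x
    bit_depth: int = 16

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.cell_radius_mean <= 0:
            raise ValueError("cell radii must be positive")


@dataclass
class NoiseModel:
    shot_noise: bool = True
    read_noise_sd: float = 2.0

    def __post_init__(self):
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class TrueCell:
    label: int
    cls: str  # "baseline" | "induced"
    intensity: float  # counts above background
    center: tuple[float, float]  # (x, y) px
    radius: float
    area_px: int


@dataclass
class GroundTruth:
    """Per-cell truth for one rendered field."""

    cells: list[TrueCell]
    induced_fraction: float
    seed: int


@dataclass
class GrowthParams:
    initial_od: float = 0.2
    doubling_time: float = 8.0  # hours; slow growth in minimal medium
    carrying_capacity: float = 4.0

    def __post_init__(self):
        if self.initial_od <= 0 or self.doubling_time <= 0:
            raise ValueError("initial_od and doubling_time must be > 0")
        if self.carrying_capacity < self.initial_od:
            raise ValueError("carrying_capacity must be >= initial_od")


@dataclass
class TFTrajectoryParams:
    """Log-logistic transformation-frequency trajectory."""

    floor_tf: float = 1e-8
    peak_tf: float = 1e-2
    onset_time: float = 12.0  # hours
    max_log_slope: float = 0.5  # log10 frequency per hour

    def __post_init__(self):
        if not (0 < self.floor_tf <= self.peak_tf <= 1.0):
            raise ValueError("require 0 < floor_tf <= peak_tf <= 1")
        if self.max_log_slope < 0:
            raise ValueError("max_log_slope must be >= 0")


@dataclass
class ReporterParams:
    """Reporter-assay generative parameters.

    The normalized (MUG / Nile Red) signal follows ``fourpl``; the raw
    MUG signal is that curve times biomass, capped at
    ``substrate_capacity`` after which it decays at ``decay_rate`` as
    the fluorogenic substrate depletes.  Nile Red is proportional to
    biomass (logistic growth when ``growth`` is given, constant
    otherwise).
    """

    fourpl: FourPLParams
    substrate_capacity: float = np.inf  # fluorescence counts
    decay_rate: float = 0.0  # per hour
    meas_noise_sd: float = 0.0  # relative (multiplicative) units
    growth: GrowthParams | None = None
    nilered_scale: float = 1000.0  # counts per OD unit

    def __post_init__(self):
        if self.substrate_capacity <= 0:
            raise ValueError("substrate_capacity must be > 0")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")


# ---------------------------------------------------------------------------
# single-cell intensity draws and field rendering
# ---------------------------------------------------------------------------


def draw_intensities(
    model: MixtureModel, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` linear-scale intensities and class labels from the mixture.

    Returns (values, labels) with labels in {"baseline", "induced"};
    values are 10**Normal(log_mean, log_sd) per component.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    induced = rng.random(n) < model.induced_fraction
    log_vals = np.where(
        induced,
        rng.normal(model.induced_log_mean, model.induced_log_sd, n),
        rng.normal(model.baseline_log_mean, model.baseline_log_sd, n),
    )
    labels = np.where(induced, "induced", "baseline")
    return 10.0**log_vals, labels


def _place_cells(
    geometry: FieldGeometry, rng: np.random.Generator, retry_cap: int = 200000
) -> list[tuple[float, float, float]]:
    """Rejection-sample non-overlapping disk centers and radii."""
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < geometry.n_cells:
        if attempts >= retry_cap:
            raise RuntimeError(
                f"could not place {geometry.n_cells} non-overlapping cells in a "
                f"{geometry.width}x{geometry.height} field after {retry_cap} "
                "attempts; reduce cell density or enlarge the field"
            )
        attempts += 1
        r = max(1.0, rng.normal(geometry.cell_radius_mean, geometry.cell_radius_sd))
        x = rng.uniform(r + 1, geometry.width - r - 1)
        y = rng.uniform(r + 1, geometry.height - r - 1)
        ok = all(
            (x - px) ** 2 + (y - py) ** 2 > (r + pr + 1.0) ** 2
            for px, py, pr in placed
        )
        if ok:
            placed.append((x, y, r))
    return placed


def render_field(
    geometry: FieldGeometry,
    intensities: Sequence[float],
    noise: NoiseModel,
    seed: int,
    labels: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Render a raw field image, its label mask, and the ground truth.

    Each cell is a disk of constant expected intensity added to the
    background (level plus optional linear gradient along x, which
    exercises per-image normalization downstream).  Shot noise draws
    Poisson counts from the expected image; read noise adds Gaussian
    counts.  The image is clipped and rounded into ``bit_depth``.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.size != geometry.n_cells:
        raise ValueError("n_cells must equal the number of intensities")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : geometry.height, 0 : geometry.width]
    expected = geometry.background_level + geometry.background_gradient * xx.astype(float)
    mask = np.zeros((geometry.height, geometry.width), dtype=np.int32)
    cells: list[TrueCell] = []
    placed = _place_cells(geometry, rng)
    for i, ((x, y, r), inten) in enumerate(zip(placed, intensities), start=1):
        disk = (xx - x) ** 2 + (yy - y) ** 2 <= r**2
        expected[disk] += inten
        mask[disk] = i
        cells.append(
            TrueCell(
                label=i,
                cls=str(labels[i - 1]) if labels is not None else "baseline",
                intensity=float(inten),
                center=(float(x), float(y)),
                radius=float(r),
                area_px=int(disk.sum()),
            )
        )
    img = rng.poisson(expected).astype(float) if noise.shot_noise else expected.copy()
    if noise.read_noise_sd > 0:
        img = img + rng.normal(0.0, noise.read_noise_sd, img.shape)
    max_val = 2**geometry.bit_depth - 1
    img = np.clip(np.rint(img), 0, max_val)
    dtype = np.uint8 if geometry.bit_depth <= 8 else np.uint16
    induced_frac = (
        float(np.mean([c.cls == "induced" for c in cells])) if cells else 0.0
    )
    gt = GroundTruth(cells=cells, induced_fraction=induced_frac, seed=seed)
    return img.astype(dtype), mask, gt


def match_to_ground_truth(
    gt_mask: np.ndarray, seg: SegmentationResult
) -> dict:
    """Match segmented objects to ground-truth mask labels.

    A predicted object claims the ground-truth label under its centroid
    (coccoid cells are convex, so the centroid lies inside the true
    disk for a correct detection).  Returns detection and spurious
    counts plus the (gt_label, pred_label) pairs for intensity-recovery
    checks.
    """
    pairs = []
    spurious = 0
    claimed: set[int] = set()
    for o in seg.objects:
        r, c = int(round(o.centroid_y)), int(round(o.centroid_x))
        r = min(max(r, 0), gt_mask.shape[0] - 1)
        c = min(max(c, 0), gt_mask.shape[1] - 1)
        gt_label = int(gt_mask[r, c])
        if gt_label == 0 or gt_label in claimed:
            spurious += 1
        else:
            claimed.add(gt_label)
            pairs.append((gt_label, o.label))
    n_true = int(gt_mask.max())
    return {
        "n_true": n_true,
        "n_detected": len(claimed),
        "n_spurious": spurious,
        "pairs": pairs,
    }


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------


def simulate_fc_sample(
    model: MixtureModel,
    n_events: int = 100_000,
    seed: int = 0,
    strain: str = "",
    timepoint_h: float = 0.0,
    channel: str = "PE-A",
) -> EventTable:
    """Simulate one flow-cytometry sample (linear-scale channel values)."""
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    values, labels = draw_intensities(model, n_events, seed)
    return EventTable(
        strain=strain,
        timepoint_h=timepoint_h,
        channel=channel,
        values=values,
        meta={
            "seed": seed,
            "true_induced_fraction": model.induced_fraction,
            "true_induced_count": int(np.sum(labels == "induced")),
        },
    )


# ---------------------------------------------------------------------------
# population kinetics
# ---------------------------------------------------------------------------


def simulate_growth(params: GrowthParams, times) -> np.ndarray:
    """Logistic OD600 series; early phase doubles every ``doubling_time``."""
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be nondecreasing")
    r = np.log(2.0) / params.doubling_time
    k, n0 = params.carrying_capacity, params.initial_od
    return k * n0 * np.exp(r * t) / (k + n0 * (np.exp(r * t) - 1.0))


def simulate_tf_trajectory(params: TFTrajectoryParams, times) -> np.ndarray:
    """True transformation-frequency trajectory, logistic on the log10 scale.

    The curve rises from ``floor_tf`` to ``peak_tf`` with its maximum
    log10 slope ``max_log_slope`` attained at ``onset_time``.
    """
    t = np.asarray(times, dtype=float)
    lo, hi = np.log10(params.floor_tf), np.log10(params.peak_tf)
    if hi == lo or params.max_log_slope == 0:
        return np.full_like(t, params.floor_tf)
    k = 4.0 * params.max_log_slope / (hi - lo)
    log_tf = lo + (hi - lo) / (1.0 + np.exp(-k * (t - params.onset_time)))
    return 10.0**log_tf


def simulate_plating(
    tf_true,
    times,
    total_cfu_per_plate: float,
    reversion_rate: float,
    seed: int,
    condition: str = "",
) -> list[PlateCount]:
    """Simulate selective/total/no-DNA-control platings along a trajectory.

    Selective counts are Poisson with mean total x (tf + reversion);
    control counts Poisson with mean total x reversion; the total-plate
    count is Poisson around the plated total.
    """
    tf_true = np.asarray(tf_true, dtype=float)
    if np.any((tf_true < 0) | (tf_true > 1)):
        raise ValueError("tf_true must lie in [0, 1]")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    counts = []
    for ti, tfi in zip(t, tf_true):
        total = max(int(rng.poisson(total_cfu_per_plate)), 1)
        counts.append(
            PlateCount(
                condition=condition,
                time_h=float(ti),
                selective_cfu=int(rng.poisson(total_cfu_per_plate * (tfi + reversion_rate))),
                total_cfu=total,
                control_selective_cfu=int(
                    rng.poisson(total_cfu_per_plate * reversion_rate)
                ),
                control_total_cfu=max(int(rng.poisson(total_cfu_per_plate)), 1),
            )
        )
    return counts


def simulate_reporter(
    params: ReporterParams, times, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate raw MUG and Nile-Red fluorescence series.

    Noiseless with infinite capacity and zero decay, MUG/NileRed equals
    the 4PL exactly.  Once raw MUG reaches ``substrate_capacity`` it is
    capped there and decays exponentially at ``decay_rate``.
    """
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be nondecreasing")
    rng = np.random.default_rng(seed)
    if params.growth is not None:
        biomass = simulate_growth(params.growth, t) * params.nilered_scale
    else:
        biomass = np.full_like(t, params.nilered_scale)
    p = params.fourpl
    mug = biomass * fourpl(t, p.a, p.d, p.c, p.b)
    hit = np.nonzero(mug >= params.substrate_capacity)[0]
    if hit.size:
        i0 = hit[0]
        t_dep = t[i0]
        mug[i0:] = params.substrate_capacity * np.exp(
            -params.decay_rate * (t[i0:] - t_dep)
        )
    if params.meas_noise_sd > 0:
        mug = mug * (1.0 + rng.normal(0.0, params.meas_noise_sd, t.shape))
        biomass = biomass * (1.0 + rng.normal(0.0, params.meas_noise_sd, t.shape))
    return mug, biomass


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class StrainSpec:
    """One strain's mixture base and induced-fraction schedule."""

    name: str
    baseline_log_mean: float
    baseline_log_sd: float
    induced_log_mean: float
    induced_log_sd: float
    induced_fraction_by_time: dict[float, float]

    def mixture_at(self, timepoint_h: float) -> MixtureModel:
        if timepoint_h not in self.induced_fraction_by_time:
            raise KeyError(
                f"strain {self.name!r} has no induced fraction at t={timepoint_h} h"
            )
        return MixtureModel(
            self.baseline_log_mean,
            self.baseline_log_sd,
            self.induced_log_mean,
            self.induced_log_sd,
            self.induced_fraction_by_time[timepoint_h],
        )


@dataclass
class Scenario:
    """A full synthetic study: strains x timepoints, FC + microscopy + kinetics."""

    seed: int = 0
    timepoints: tuple[float, ...] = (2.0, 7.0, 20.0)
    strains: list[StrainSpec] = field(default_factory=list)
    fc_events: int = 100_000
    fields_per_sample: int = 6
    geometry: FieldGeometry = field(default_factory=FieldGeometry)
    noise: NoiseModel = field(default_factory=NoiseModel)
    growth: GrowthParams = field(default_factory=GrowthParams)
    tf_trajectory: TFTrajectoryParams = field(default_factory=TFTrajectoryParams)
    plating_total_cfu: float = 1e9
    reversion_rate: float = 1e-9
    reporter: ReporterParams | None = None
    include_microscopy: bool = True

    def stage_seed(self, *tags) -> int:
        """Deterministic per-stage seed derived from the scenario seed.

        Tags hash through a stable digest so derived seeds do not depend
        on interpreter hash randomization.
        """
        digest = hashlib.sha256("/".join(str(t) for t in tags).encode()).digest()
        tag_key = int.from_bytes(digest[:4], "little")
        ss = np.random.SeedSequence([self.seed, tag_key])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def default_scenario(seed: int = 0, **overrides) -> Scenario:
    """The default synthetic study conditions.

    Three strains mirror the experimental design: a competence reporter
    whose induced fraction grows 0 -> 0.05 over three timepoints, a
    non-fluorescent wild type, and a constitutive-promoter control, both
    with a flat zero induced fraction.  FC samples carry 100,000 events;
    microscopy uses 6 fields of ~60 cells per strain and timepoint.
    """
    tps = overrides.pop("timepoints", (2.0, 7.0, 20.0))
    strains = overrides.pop(
        "strains",
        [
            StrainSpec(
                name="comEA_reporter",
                baseline_log_mean=2.8,
                baseline_log_sd=0.12,
                induced_log_mean=3.6,
                induced_log_sd=0.12,
                induced_fraction_by_time={tps[0]: 0.0, tps[1]: 0.01, tps[2]: 0.05},
            ),
            StrainSpec(
                name="wildtype",
                baseline_log_mean=2.5,
                baseline_log_sd=0.10,
                induced_log_mean=3.3,
                induced_log_sd=0.10,
                induced_fraction_by_time={t: 0.0 for t in tps},
            ),
            StrainSpec(
                name="constitutive",
                baseline_log_mean=3.0,
                baseline_log_sd=0.10,
                induced_log_mean=3.8,
                induced_log_sd=0.10,
                induced_fraction_by_time={t: 0.0 for t in tps},
            ),
        ],
    )
    geometry = overrides.pop("geometry", FieldGeometry(n_cells=60))
    reporter = overrides.pop(
        "reporter",
        ReporterParams(
            fourpl=FourPLParams(a=0.05, d=1.0, c=12.0, b=4.0),
            substrate_capacity=5e5,
            decay_rate=0.05,
            meas_noise_sd=0.02,
            growth=GrowthParams(),
        ),
    )
    return Scenario(
        seed=seed,
        timepoints=tuple(tps),
        strains=strains,
        geometry=geometry,
        reporter=reporter,
        **overrides,
    )


@dataclass
class FieldSample:
    image: np.ndarray
    mask: np.ndarray
    ground_truth: GroundTruth
    strain: str
    timepoint_h: float
    field_index: int


@dataclass
class ScenarioResult:
    scenario: Scenario
    fc_samples: list[EventTable]
    microscopy: list[FieldSample]
    growth_times: np.ndarray
    od: np.ndarray
    plate_counts: list[PlateCount]
    reporter_times: np.ndarray
    mug: np.ndarray
    nilered: np.ndarray
    stage_seeds: dict[str, int]


def simulate_scenario(scn: Scenario) -> ScenarioResult:
    """Run every generator stage of a scenario with derived seeds."""
    stage_seeds: dict[str, int] = {}
    fc_samples = []
    microscopy: list[FieldSample] = []
    for strain in scn.strains:
        for tp in scn.timepoints:
            model = strain.mixture_at(tp)
            s_fc = scn.stage_seed("fc", strain.name, tp)
            stage_seeds[f"fc/{strain.name}/t{tp:g}"] = s_fc
            fc_samples.append(
                simulate_fc_sample(
                    model,
                    n_events=scn.fc_events,
                    seed=s_fc,
                    strain=strain.name,
                    timepoint_h=tp,
                )
            )
            if scn.include_microscopy:
                for f in range(scn.fields_per_sample):
                    s_img = scn.stage_seed("img", strain.name, tp, f)
                    stage_seeds[f"img/{strain.name}/t{tp:g}/f{f}"] = s_img
                    vals, labels = draw_intensities(model, scn.geometry.n_cells, s_img)
                    img, mask, gt = render_field(
                        scn.geometry, vals, scn.noise, seed=s_img + 1, labels=labels
                    )
                    microscopy.append(
                        FieldSample(
                            image=img,
                            mask=mask,
                            ground_truth=gt,
                            strain=strain.name,
                            timepoint_h=tp,
                            field_index=f,
                        )
                    )
    growth_times = np.arange(0.0, 30.0 + 1e-9, 2.0)
    od = simulate_growth(scn.growth, growth_times)
    tf_true = simulate_tf_trajectory(scn.tf_trajectory, growth_times)
    s_plate = scn.stage_seed("plating")
    stage_seeds["plating"] = s_plate
    plate_counts = simulate_plating(
        tf_true,
        growth_times,
        total_cfu_per_plate=scn.plating_total_cfu,
        reversion_rate=scn.reversion_rate,
        seed=s_plate,
        condition=f"od{scn.growth.initial_od:g}",
    )
    reporter_times = np.arange(0.0, 30.0 + 1e-9, 0.5)
    if scn.reporter is not None:
        s_rep = scn.stage_seed("reporter")
        stage_seeds["reporter"] = s_rep
        mug, nilered = simulate_reporter(scn.reporter, reporter_times, seed=s_rep)
    else:
        mug = nilered = np.array([])
    return ScenarioResult(
        scenario=scn,
        fc_samples=fc_samples,
        microscopy=microscopy,
        growth_times=growth_times,
        od=od,
        plate_counts=plate_counts,
        reporter_times=reporter_times,
        mug=mug,
        nilered=nilered,
        stage_seeds=stage_seeds,
    )


# ---------------------------------------------------------------------------
# YAML scenario configs
# ---------------------------------------------------------------------------

_SCENARIO_KEYS = {
    "seed",
    "timepoints",
    "strains",
    "fc_events",
    "fields_per_sample",
    "geometry",
    "noise",
    "growth",
    "tf_trajectory",
    "plating_total_cfu",
    "reversion_rate",
    "reporter",
    "include_microscopy",
}


def scenario_from_dict(cfg: Mapping) -> Scenario:
    """Build a scenario from a parsed YAML mapping; unknown keys rejected."""
    unknown = set(cfg) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    kwargs = dict(cfg)
    if "timepoints" in kwargs:
        kwargs["timepoints"] = tuple(float(t) for t in kwargs["timepoints"])
    if "strains" in kwargs:
        kwargs["strains"] = [
            StrainSpec(
                name=s["name"],
                baseline_log_mean=s["baseline_log_mean"],
                baseline_log_sd=s["baseline_log_sd"],
                induced_log_mean=s["induced_log_mean"],
                induced_log_sd=s["induced_log_sd"],
                induced_fraction_by_time={
                    float(k): float(v) for k, v in s["induced_fraction_by_time"].items()
                },
            )
            for s in kwargs["strains"]
        ]
    if "geometry" in kwargs:
        kwargs["geometry"] = FieldGeometry(**kwargs["geometry"])
    if "noise" in kwargs:
        kwargs["noise"] = NoiseModel(**kwargs["noise"])
    if "growth" in kwargs:
        kwargs["growth"] = GrowthParams(**kwargs["growth"])
    if "tf_trajectory" in kwargs:
        kwargs["tf_trajectory"] = TFTrajectoryParams(**kwargs["tf_trajectory"])
    if "reporter" in kwargs and kwargs["reporter"] is not None:
        rep = dict(kwargs["reporter"])
        rep["fourpl"] = FourPLParams(**rep["fourpl"])
        if rep.get("growth") is not None:
            rep["growth"] = GrowthParams(**rep["growth"])
        kwargs["reporter"] = ReporterParams(**rep)
    base = default_scenario(seed=int(kwargs.pop("seed", 0)))
    for k, v in kwargs.items():
        setattr(base, k, v)
    return base


def load_scenario(path) -> Scenario:
    """Load a YAML scenario config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ValueError("scenario config must be a mapping")
    return scenario_from_dict(cfg)
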