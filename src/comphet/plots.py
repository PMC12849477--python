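"""Beeswarm-style figures for single-cell shift reports.

One panel per strain: jittered points (one per subsampled event/cell),
dashed horizontal lines at the reference-anchored thresholds, and an
annotation box with the delta_pp values — the standard layout for
reference-thresholded single-cell distribution comparisons.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .heterogeneity_stats import SampleDistribution, ShiftReport, subsample_for_display


def plot_shift_beeswarm(
    samples: Iterable[SampleDistribution],
    report: ShiftReport,
    out_path,
    subsample_n: int = 250,
    seed: int = 0,
) -> Path:
    """Render the shift report as per-strain beeswarm panels.

    Display subsampling (uniform without replacement, seeded) only
    affects the plotted points; all annotated statistics come from the
    report, which was computed from the full samples.
    """
    samples = list(samples)
    strains = sorted({s.strain for s in samples})
    fig, axes = plt.subplots(
        1, len(strains), figsize=(3.2 * len(strains), 4.2), sharey=True, squeeze=False
    )
    rng = np.random.default_rng(seed)
    for ax, strain in zip(axes[0], strains):
        strain_samples = sorted(
            (s for s in samples if s.strain == strain), key=lambda s: s.timepoint_h
        )
        for i, s in enumerate(strain_samples):
            sub = subsample_for_display(s, min(subsample_n, s.n), seed=seed + i)
            jitter = rng.uniform(-0.25, 0.25, sub.n)
            ax.plot(
                np.full(sub.n, i) + jitter,
                sub.values,
                ".",
                markersize=2,
                alpha=0.6,
            )
        ts = report.thresholds[strain]
        for level, thr in zip(ts.quantile_levels, ts.thresholds):
            ax.axhline(thr, linestyle="--", linewidth=0.9, color="navy", alpha=0.7)
            ax.annotate(
                f"p{level:g}",
                xy=(len(strain_samples) - 0.5, thr),
                fontsize=7,
                color="navy",
            )
        deltas = report.deltas[report.deltas["strain"] == strain]
        text = "\n".join(
            f"Δ p{row.level:g}: {row.delta_pp:+.2f} pp" for row in deltas.itertuples()
        )
        ax.text(
            0.03,
            0.97,
            text,
            transform=ax.transAxes,
            va="top",
            fontsize=8,
            bbox={"boxstyle": "round", "facecolor": "white", "alpha": 0.8},
        )
        ax.set_xticks(range(len(strain_samples)))
        ax.set_xticklabels([f"{s.timepoint_h:g} h" for s in strain_samples])
        ax.set_title(strain, fontsize=9)
    scale = samples[0].scale if samples else ""
    axes[0][0].set_ylabel(
        "log10 fluorescence" if scale == "log10_fluorescence" else "relative intensity (%)"
    )
    fig.tight_layout()
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
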