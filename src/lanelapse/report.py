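"""Report and figure generation for a cohort analysis.

``analyze_cohort`` writes, into an output directory:

* ``age_boxplots.csv`` / ``age_boxplots.png`` — per-age boxplot table and
  figure of absolute error;
* ``error_over_time_age<A>.png`` — per-age error trajectories;
* ``scree_age<A>.csv`` / ``.png`` and ``assignments_age<A>.csv`` — scree
  tables, plots and cluster memberships per age with >= 2 participants;
* ``attention_<pid>.json`` and ``triptych_<pid>.png`` — per-participant
  attention report (fences, sustained runs, first loss, totals) and the
  three-panel figure (group boxplot, outlier-marked trajectory,
  sustained-error trajectory);
* ``summary.json`` — cohort-level roll-up;
* ``provenance.json`` — config, seed and package version.

Tests assert on the numeric sidecar files, never on pixels.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import __version__
from .attention import compute_attention, group_fences, outlier_mask, sustained_runs
from .clustering import cluster_age_group
from .error_stats import age_boxplot_table, age_boxplot_frame, age_grouped_positions
from .session_io import Cohort

logger = logging.getLogger(__name__)


def write_provenance(outdir: Path, config: dict) -> None:
    (outdir / "provenance.json").write_text(
        json.dumps({"version": __version__, **config}, indent=2, sort_keys=True)
    )


def age_boxplot_figure(cohort: Cohort, path: Path) -> None:
    ages = cohort.ages()
    data = [age_grouped_positions(cohort, a, signed=False) for a in ages]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.boxplot(data, tick_labels=[str(a) for a in ages], sym="r.", flierprops={"ms": 1})
    ax.set_xlabel("age (years)")
    ax.set_ylabel("absolute error (m)")
    ax.set_title("Absolute lateral error by age")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def error_over_time_figure(cohort: Cohort, age: int, path: Path) -> None:
    sessions = cohort.by_age(age)
    fig, axes = plt.subplots(
        len(sessions), 1, figsize=(8, 1.4 * len(sessions)), sharex=True, squeeze=False
    )
    for ax, s in zip(axes.ravel(), sessions):
        t_min = s.t / 60.0
        ax.plot(t_min, np.abs(s.positions), lw=0.4)
        ax.set_ylabel(s.participant_id, rotation=0, ha="right", fontsize=8)
    axes.ravel()[-1].set_xlabel("time (min)")
    fig.suptitle(f"Error over time, age {age}")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def scree_figure(ks, inertias, selected_k: int, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ks, inertias, "o-")
    ax.axvline(selected_k, color="r", ls="--", lw=1, label=f"selected k={selected_k}")
    ax.set_xlabel("number of clusters k")
    ax.set_ylabel("within-cluster inertia")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def triptych_figure(cohort: Cohort, participant_id: str, path: Path,
                    min_duration_s: float = 1.0) -> None:
    """Three-panel attention figure: age-group boxplot of signed
    positions, outlier-marked trajectory, sustained-error trajectory."""
    session = cohort.get(participant_id)
    age = int(session.age)
    fences = group_fences(cohort, age)
    mask = outlier_mask(session, fences)
    runs = sustained_runs(mask, min_duration=min_duration_s)
    t_min = session.t / 60.0

    fig, (ax1, ax2, ax3) = plt.subplots(1, 3, figsize=(13, 3.5),
                                        gridspec_kw={"width_ratios": [1, 3, 3]})
    pooled = age_grouped_positions(cohort, age, signed=True)
    ax1.boxplot([pooled], sym="r.", flierprops={"ms": 1})
    ax1.set_title(f"positions, age {age}")
    ax1.set_ylabel("position (m)")

    ax2.plot(t_min, session.positions, lw=0.4, color="0.3")
    ax2.plot(t_min[mask.mask], session.positions[mask.mask], "r.", ms=1)
    ax2.axhline(fences[0], color="b", lw=0.6, ls=":")
    ax2.axhline(fences[1], color="b", lw=0.6, ls=":")
    ax2.set_title(f"{participant_id}: outlying positions")
    ax2.set_xlabel("time (min)")

    ax3.plot(t_min, session.positions, lw=0.4, color="0.3")
    for r in runs:
        sl = slice(r.start_index, r.end_index)
        ax3.plot(t_min[sl], session.positions[sl], "r", lw=0.6)
    ax3.set_title("sustained errors (>= 1 s)")
    ax3.set_xlabel("time (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def analyze_cohort(
    cohort: Cohort,
    outdir: str | Path,
    seed: int = 0,
    bin_width: float = 10.0,
    min_lapse_seconds: float = 1.0,
    k_max: int = 6,
    leave_one_out_fences: bool = False,
    figures: bool = True,
) -> dict:
    """Run the full analysis chain and write the report directory.

    Returns the cohort-level summary dict (also written to
    ``summary.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_provenance(
        outdir,
        {
            "seed": seed,
            "bin_width": bin_width,
            "min_lapse_seconds": min_lapse_seconds,
            "k_max": k_max,
            "leave_one_out_fences": leave_one_out_fences,
            "n_participants": len(cohort),
        },
    )

    table = age_boxplot_table(cohort)
    age_boxplot_frame(table).to_csv(outdir / "age_boxplots.csv", index=False)
    if figures:
        age_boxplot_figure(cohort, outdir / "age_boxplots.png")

    clusters: dict[int, dict] = {}
    for age in cohort.ages():
        if figures:
            error_over_time_figure(cohort, age, outdir / f"error_over_time_age{age}.png")
        if len(cohort.by_age(age)) < 2:
            logger.info("age %d has a single participant; skipping clustering", age)
            continue
        result = cluster_age_group(cohort, age, k_max=k_max, seed=seed,
                                   bin_width=bin_width)
        result.scree_frame().to_csv(outdir / f"scree_age{age}.csv", index=False)
        result.assignments_frame().to_csv(
            outdir / f"assignments_age{age}.csv", index=False
        )
        if figures:
            scree_figure(result.k_values, result.inertias, result.selected_k,
                         outdir / f"scree_age{age}.png")
        clusters[age] = {
            "selected_k": result.selected_k,
            "singletons": list(result.singletons),
            "no_structure": result.no_structure,
        }

    profiles = {}
    for pid in cohort.participant_ids:
        profile = compute_attention(
            cohort, pid, min_duration_s=min_lapse_seconds,
            leave_one_out=leave_one_out_fences,
        )
        doc = profile.to_dict()
        (outdir / f"attention_{pid}.json").write_text(json.dumps(doc, indent=2))
        if figures:
            triptych_figure(cohort, pid, outdir / f"triptych_{pid}.png",
                            min_duration_s=min_lapse_seconds)
        profiles[pid] = doc

    summary = {
        "n_participants": len(cohort),
        "ages": cohort.ages(),
        "age_boxplots": {str(a): st.to_dict() for a, st in table.items()},
        "clusters": {str(a): c for a, c in clusters.items()},
        "n_with_sustained_errors": sum(
            1 for p in profiles.values() if p["runs"]
        ),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
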