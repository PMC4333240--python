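"""Drivers for the two assumption experiments, plus table/plot output.

Both experiments perturb a single assumption about LTin cell entry and
compare every perturbed condition against the calibrated baseline with the
Vargha-Delaney A-Test, on the two per-run responses (patch count, median
patch area):

* the cell-count experiment varies the E15.5 surface-area fraction
  (0.05-0.45 % in 0.05 % steps) and applies 2-5 fold increases of the
  baseline count;
* the migration-rate experiment swaps the linear entry schedule for an
  exponential or square-root one, all anchored to the same E15.5 count.

Baseline and perturbed conditions use disjoint replicate seed streams, so
each comparison is between independent distributions (no common-random-
number pairing).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .config import SimConfig, save_config
from .engine import RESPONSES, ConditionResult, run_replicates
from .stats import a_test

logger = logging.getLogger("ppsim")

DEFAULT_FRACTIONS = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45)
DEFAULT_FOLDS = (2, 3, 4, 5)
SCHEDULE_FORMS = ("linear", "exponential", "sqrt")

TABLE_COLUMNS = [
    "condition",
    "response",
    "a_vs_baseline",
    "magnitude",
    "category",
    "n_reps",
    "base_seed",
]


@dataclass
class ExperimentTable:
    """Summary table plus the per-condition run distributions behind it."""

    summary: pd.DataFrame  # columns TABLE_COLUMNS
    conditions: dict[str, ConditionResult] = field(default_factory=dict)
    baseline_label: str = "baseline"
    config: SimConfig | None = None


def _condition_differs_in_one_subtree(base: SimConfig, cond: SimConfig) -> None:
    """Guard: a perturbed condition must differ from baseline in exactly one
    configuration subtree (every experiment here perturbs only ``input``)."""
    bd, cd = base.to_dict(), cond.to_dict()
    changed = [k for k in bd if bd[k] != cd[k]]
    if len(changed) > 1:
        raise ValueError(
            f"condition differs from baseline in multiple subtrees: {changed}"
        )


def _run_conditions(
    base: SimConfig,
    conditions: list[tuple[str, SimConfig]],
    n_reps: int,
    base_seed: int,
) -> ExperimentTable:
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 to form distributions")
    results: dict[str, ConditionResult] = {}
    for ci, (label, cfg) in enumerate(conditions):
        _condition_differs_in_one_subtree(base, cfg)
        cond_seed = _condition_seed(base_seed, ci)
        t0 = time.perf_counter()
        results[label] = run_replicates(cfg, n_reps, cond_seed, label=label)
        logger.info(
            "condition %s: %d reps, seed %d, %.1f s",
            label, n_reps, cond_seed, time.perf_counter() - t0,
        )

    baseline_label = conditions[0][0]
    baseline = results[baseline_label]
    rows = []
    for label, _ in conditions:
        for resp in RESPONSES:
            res = a_test(results[label].response(resp), baseline.response(resp))
            rows.append(
                {
                    "condition": label,
                    "response": resp,
                    "a_vs_baseline": res.a,
                    "magnitude": res.magnitude,
                    "category": res.category,
                    "n_reps": n_reps,
                    "base_seed": base_seed,
                }
            )
    return ExperimentTable(
        summary=pd.DataFrame(rows, columns=TABLE_COLUMNS),
        conditions=results,
        baseline_label=baseline_label,
        config=base,
    )


def _condition_seed(base_seed: int, condition_index: int) -> int:
    # disjoint seed stream per condition; replicate seeds derive from this
    import numpy as np

    ss = np.random.SeedSequence([int(base_seed), 7919, int(condition_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def cellcount_experiment(
    base: SimConfig,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    folds: Sequence[float] = DEFAULT_FOLDS,
    n_reps: int = 300,
    base_seed: int = 0,
) -> ExperimentTable:
    """Perturb the E15.5 LTin count: reduced area fractions and fold increases.

    ``fractions`` are percentages of gut surface area; the baseline fraction
    (from ``base.input.fraction_pct``) is added to the grid if missing and
    always listed first.  Fold conditions multiply the baseline E15.5 count.
    """
    base_frac = base.input.fraction_pct
    fracs = sorted(set(float(f) for f in fractions) | {base_frac}, reverse=True)
    conditions: list[tuple[str, SimConfig]] = []
    for f in fracs:
        label = "baseline" if f == base_frac else f"frac_{f:.2f}"
        conditions.append((label, base.replace(input={"fraction_pct": f})))
    for k in folds:
        conditions.append((f"fold_{k:g}", base.replace(input={"fold": float(k)})))
    # baseline first so every comparison sees it
    conditions.sort(key=lambda c: c[0] != "baseline")
    return _run_conditions(base, conditions, n_reps, base_seed)


def migration_experiment(
    base: SimConfig,
    forms: Sequence[str] = SCHEDULE_FORMS,
    n_reps: int = 300,
    base_seed: int = 0,
) -> ExperimentTable:
    """Swap the LTin entry-schedule form, keeping the E15.5 anchor fixed."""
    for f in forms:
        if f not in SCHEDULE_FORMS:
            raise ValueError(f"unknown schedule form {f!r}")
    base_form = base.input.form
    ordered = [base_form] + [f for f in forms if f != base_form]
    conditions = [
        (
            "baseline" if f == base_form else f"input_{f}",
            base.replace(input={"form": f}),
        )
        for f in ordered
    ]
    return _run_conditions(base, conditions, n_reps, base_seed)


# -- output -----------------------------------------------------------------

RUN_COLUMNS = [
    "condition_label",
    "replicate_index",
    "seed",
    "patch_count",
    "median_patch_area_um2",
    "total_cells_in",
]


def condition_to_dataframe(cond: ConditionResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "condition_label": cond.label,
                "replicate_index": i,
                "seed": r.seed,
                "patch_count": r.patch_count,
                "median_patch_area_um2": r.median_patch_area,
                "total_cells_in": r.total_cells_in,
            }
            for i, r in enumerate(cond.runs)
        ],
        columns=RUN_COLUMNS,
    )


def write_table(table: ExperimentTable, path: str | Path) -> None:
    """Write the experiment summary as CSV (columns exactly TABLE_COLUMNS)."""
    if len(table.summary) == 0:
        raise ValueError("refusing to write an empty experiment table")
    table.summary.to_csv(path, index=False)


def write_experiment(table: ExperimentTable, out_dir: str | Path) -> Path:
    """Write a full experiment: summary.csv, per-condition CSVs, config, plots."""
    out = Path(out_dir)
    (out / "conditions").mkdir(parents=True, exist_ok=True)
    write_table(table, out / "summary.csv")
    for label, cond in table.conditions.items():
        condition_to_dataframe(cond).to_csv(
            out / "conditions" / f"{label}.csv", index=False
        )
    if table.config is not None:
        save_config(table.config, out / "config_snapshot.yaml")
    plot_experiment(table, out / "plots")
    return out


def plot_experiment(table: ExperimentTable, out_dir: str | Path) -> list[Path]:
    """Boxplots of the per-condition response distributions and an A-score
    chart with guides at the effect-band edges (0.29, 0.44, 0.56, 0.71)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    labels = list(table.conditions)

    for resp, unit in (("patch_count", "patches"), ("median_patch_area", "um^2")):
        fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
        ax.boxplot(
            [table.conditions[l].response(resp) for l in labels],
            tick_labels=labels,
        )
        ax.set_ylabel(f"{resp} ({unit})")
        ax.set_title(f"Per-run {resp} by condition")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        p = out / f"boxplot_{resp}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    fig, ax = plt.subplots(figsize=(1.2 * len(labels) + 2, 4))
    for resp, marker in (("patch_count", "o"), ("median_patch_area", "s")):
        sub = table.summary[table.summary["response"] == resp]
        ax.plot(
            sub["condition"], sub["a_vs_baseline"], marker, ls="-", label=resp
        )
    for guide in (0.29, 0.44, 0.56, 0.71):
        ax.axhline(guide, color="grey", lw=0.8, ls="--")
    ax.axhline(0.5, color="black", lw=0.8)
    ax.set_ylim(0, 1)
    ax.set_ylabel("A vs baseline")
    ax.legend()
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    p = out / "atest_scores.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
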