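"""Figure-style summary tables and plots.

Three summaries mirror the canonical displays of this kind of study:

* a per-condition mean-square comparison across predictors (strain
  identity vs the three interaction measures, linear richness for
  reference),
* strain contribution coefficients grouped by strain type,
* deviations from expected productivity against the interaction score,
  with the fitted line.

All numbers live in the returned tables; the plots are illustrations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import partition
from .partition import DecompositionResult, RegressionSummary


@dataclass
class ReportTables:
    mean_squares: pd.DataFrame
    mean_square_summary: pd.DataFrame
    type_coefficients: pd.DataFrame
    dev_vs_score: pd.DataFrame
    dev_regression: RegressionSummary | None


def mean_square_summary(comparison: pd.DataFrame) -> pd.DataFrame:
    """Median and geometric-mean mean square per condition x predictor."""
    def _summarise(grp: pd.DataFrame) -> pd.Series:
        ms = grp["mean_square"].to_numpy(dtype=float)
        pos = ms[ms > 0]
        return pd.Series(
            {
                "median_ms": float(np.median(ms)),
                "geomean_ms": float(np.exp(np.mean(np.log(pos)))) if pos.size else np.nan,
                "n_communities": grp["community_id"].nunique(),
            }
        )

    return (
        comparison.groupby(["condition", "response", "predictor"])
        .apply(_summarise, include_groups=False)
        .reset_index()
    )


def type_coefficient_table(
    coefficients: pd.DataFrame, strains: pd.DataFrame
) -> pd.DataFrame:
    """Strain coefficients annotated with strain type and habitat."""
    out = coefficients.merge(
        strains[["strain_id", "strain_type", "habitat"]], on="strain_id", how="left"
    )
    if out["strain_type"].isna().any():
        raise ValueError("coefficients reference strains missing from the strain table")
    return out.sort_values(
        ["response", "condition", "community_id", "strain_type"]
    ).reset_index(drop=True)


def report_summary(
    results: Sequence[DecompositionResult],
    traits: pd.DataFrame,
    summaries: pd.DataFrame,
    strains: pd.DataFrame,
    out_dir=None,
) -> ReportTables:
    """Build the three summary tables; write vector plots when out_dir given."""
    if not results:
        raise ValueError("no decomposition results to report")
    comparison = partition.compare_variants(results)
    coefs = partition.coefficients_frame(results)
    type_table = type_coefficient_table(coefs, strains)

    dev = traits.merge(
        summaries[["combination_id", "condition", "interaction_score"]],
        on=["combination_id", "condition"],
    ).dropna(subset=["dev_productivity"])
    regression = None
    if len(dev) >= 3 and dev["interaction_score"].var() > 0:
        regression = partition.relate_dev_to_score(traits, summaries)

    tables = ReportTables(
        mean_squares=comparison,
        mean_square_summary=mean_square_summary(comparison),
        type_coefficients=type_table,
        dev_vs_score=dev[
            ["combination_id", "condition", "richness", "interaction_score",
             "dev_productivity"]
        ].reset_index(drop=True),
        dev_regression=regression,
    )
    if out_dir is not None:
        _write_plots(tables, Path(out_dir))
    return tables


def _write_plots(tables: ReportTables, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(7, 4))
    order = ["linear_richness", "strain_id", "nonlinear_richness",
             "interaction_score", "combined_supernatant"]
    df = tables.mean_squares
    present = [p for p in order if p in set(df["predictor"])]
    for i, pred in enumerate(present):
        for j, cond in enumerate(sorted(df["condition"].unique())):
            vals = df.loc[
                (df["predictor"] == pred) & (df["condition"] == cond), "mean_square"
            ]
            x = np.full(len(vals), i + (j - 0.5) * 0.3)
            ax.semilogy(x + np.random.default_rng(0).uniform(-0.05, 0.05, len(vals)),
                        vals.clip(lower=1e-12), "o", ms=3, alpha=0.6,
                        label=cond if i == 0 else None)
    ax.set_xticks(range(len(present)), present, rotation=20)
    ax.set_ylabel("mean square")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "mean_squares.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    tdf = tables.type_coefficients
    types = sorted(tdf["strain_type"].unique())
    for i, t in enumerate(types):
        vals = tdf.loc[tdf["strain_type"] == t, "coefficient"]
        ax.plot(np.full(len(vals), i), vals, "o", ms=3, alpha=0.5)
        ax.plot([i - 0.2, i + 0.2], [vals.mean()] * 2, "k-", lw=2)
    ax.axhline(0.0, ls="--", c="grey", lw=1)
    ax.set_xticks(range(len(types)), types)
    ax.set_ylabel("strain coefficient")
    fig.tight_layout()
    fig.savefig(out_dir / "type_coefficients.svg")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    dev = tables.dev_vs_score
    for cond in sorted(dev["condition"].unique()):
        sel = dev[dev["condition"] == cond]
        ax.plot(sel["interaction_score"], sel["dev_productivity"], "o", ms=3,
                alpha=0.5, label=cond)
    if tables.dev_regression is not None:
        xs = np.linspace(dev["interaction_score"].min(), dev["interaction_score"].max(), 20)
        # partial fit line: slope around the grand mean
        y0 = dev["dev_productivity"].mean()
        x0 = dev["interaction_score"].mean()
        ax.plot(xs, y0 + tables.dev_regression.slope * (xs - x0), "k-", lw=2)
    ax.axhline(0.0, ls="--", c="grey", lw=1)
    ax.set_xlabel("interaction score")
    ax.set_ylabel("deviation from expected productivity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_dir / "dev_vs_score.svg")
    plt.close(fig)
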