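"""Community-functioning traits: growth/pyoverdine integrals and DEV.

Productivity and total pyoverdine production of each culture are
quantified as the trapezoidal integral of the OD600 and fluorescence
time series over the observed window (units OD600*h and RFU*h).  For
mixtures, the deviation from the monoculture expectation is

    DEV_trait = TV_mix - mean(TV_mono),

the mixture's trait value minus the mean trait value of its members'
monocultures under the same condition; positive DEV means the mixture
functions better than expected from its parts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ID_SEPARATOR, StrainCombination


class FunctioningError(ValueError):
    pass


def trait_integral(series: Sequence[tuple[float, float]] | np.ndarray) -> float:
    """Trapezoidal integral of a (timepoint_h, value) series."""
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise FunctioningError("need >= 2 (timepoint, value) pairs")
    t, v = arr[:, 0], arr[:, 1]
    if not np.all(np.isfinite(arr)):
        raise FunctioningError("non-finite series values")
    if np.any(np.diff(t) <= 0):
        raise FunctioningError("timepoints must be strictly increasing")
    return float(np.trapezoid(v, t))


def deviation_from_expected(mix_value: float, monoculture_values: Sequence[float]) -> float:
    """DEV = mixture trait minus the mean of its members' monoculture traits."""
    mono = np.asarray(monoculture_values, dtype=float)
    if mono.size == 0:
        raise FunctioningError("no monoculture values")
    return float(mix_value - np.mean(mono))


@dataclass
class TraitTables:
    """Replicate-level and across-replicate aggregated trait values."""

    replicates: pd.DataFrame
    aggregated: pd.DataFrame


def _integrate_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate trait values from time-series or endpoint rows.

    Endpoint rows (blank ``timepoint_h``) carry pre-integrated trait
    values in the od600/rfu_pvd columns; time-series rows are integrated
    with the trapezoid rule on their native grid.
    """
    endpoint = measurements["timepoint_h"].isna()
    rows = []
    if endpoint.any():
        sub = measurements[endpoint]
        dup = sub.duplicated(["combination_id", "condition", "replicate"])
        if dup.any():
            raise FunctioningError("duplicate endpoint rows for one replicate")
        for r in sub.itertuples(index=False):
            rows.append(
                {
                    "combination_id": r.combination_id,
                    "condition": r.condition,
                    "replicate": r.replicate,
                    "productivity": float(r.od600),
                    "pyoverdine": float(r.rfu_pvd),
                }
            )
    if (~endpoint).any():
        sub = measurements[~endpoint].sort_values("timepoint_h", kind="stable")
        for (cid, cond, rep), grp in sub.groupby(
            ["combination_id", "condition", "replicate"], sort=True
        ):
            t = grp["timepoint_h"].to_numpy(dtype=float)
            rows.append(
                {
                    "combination_id": cid,
                    "condition": cond,
                    "replicate": rep,
                    "productivity": trait_integral(
                        np.column_stack([t, grp["od600"].to_numpy(dtype=float)])
                    ),
                    "pyoverdine": trait_integral(
                        np.column_stack([t, grp["rfu_pvd"].to_numpy(dtype=float)])
                    ),
                }
            )
    return pd.DataFrame(rows)


def build_trait_table(
    measurements: pd.DataFrame,
    combinations: Sequence[StrainCombination],
    aggregate: str = "median",
) -> TraitTables:
    """Trait values and DEV for every declared combination x condition.

    Per replicate both integrals are computed; per combination the
    across-replicate ``aggregate`` (median by default, mean optional) is
    taken, and for mixtures DEV is computed against the same condition's
    monoculture aggregates — at replicate level (each mixture replicate
    against the monoculture aggregates) and at aggregate level.
    """
    if aggregate not in ("median", "mean"):
        raise FunctioningError(f"aggregate must be median or mean, got {aggregate!r}")
    by_id = {c.combination_id: c for c in combinations}
    undeclared = set(measurements["combination_id"]) - set(by_id)
    if undeclared:
        raise FunctioningError(f"undeclared combinations in measurements: {sorted(undeclared)[:5]}")

    reps = _integrate_replicates(measurements)
    reps["community_id"] = reps["combination_id"].map(lambda i: by_id[i].community_id)
    reps["richness"] = reps["combination_id"].map(lambda i: by_id[i].richness)

    agg = (
        reps.groupby(["combination_id", "condition"], sort=True)[
            ["productivity", "pyoverdine"]
        ]
        .agg(aggregate)
        .reset_index()
    )
    agg["community_id"] = agg["combination_id"].map(lambda i: by_id[i].community_id)
    agg["richness"] = agg["combination_id"].map(lambda i: by_id[i].richness)

    # monoculture aggregates keyed by (strain_id, condition)
    mono = agg[agg["richness"] == 1]
    mono_map = {
        (r.combination_id, r.condition): (r.productivity, r.pyoverdine)
        for r in mono.itertuples(index=False)
    }

    def _mono_values(combo: StrainCombination, cond: str) -> np.ndarray:
        try:
            return np.array(
                [mono_map[(m, cond)] for m in sorted(combo.members)], dtype=float
            )
        except KeyError as err:
            raise FunctioningError(
                f"monoculture {err} missing for DEV of {combo.combination_id}"
            ) from err

    for frame in (reps, agg):
        dev_prod = np.full(len(frame), np.nan)
        dev_pvd = np.full(len(frame), np.nan)
        for i, r in enumerate(frame.itertuples(index=False)):
            combo = by_id[r.combination_id]
            if combo.richness < 2:
                continue
            mono_vals = _mono_values(combo, r.condition)
            dev_prod[i] = deviation_from_expected(r.productivity, mono_vals[:, 0])
            dev_pvd[i] = deviation_from_expected(r.pyoverdine, mono_vals[:, 1])
        frame["dev_productivity"] = dev_prod
        frame["dev_pyoverdine"] = dev_pvd

    cols = [
        "combination_id",
        "community_id",
        "condition",
        "richness",
        "productivity",
        "pyoverdine",
        "dev_productivity",
        "dev_pyoverdine",
    ]
    return TraitTables(
        replicates=reps[["replicate"] + cols].sort_values(
            ["combination_id", "condition", "replicate"]
        ).reset_index(drop=True),
        aggregated=agg[cols].sort_values(["combination_id", "condition"]).reset_index(
            drop=True
        ),
    )
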