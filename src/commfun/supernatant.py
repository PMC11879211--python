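"""Directed supernatant growth effects and interaction summaries.

A donor strain's sterile spent medium is fed to a receiver strain and the
receiver's growth is compared with growth under a saline (spent-medium
mimicking) control.  The growth effect is the ratio of median growth
across replicates, ``GE = median(SN_treatment) / median(SN_control)``:
values above one indicate stimulation, below one inhibition.  Each
directed effect is classified as +1 / 0 / -1 by testing whether the
treatment replicates differ from the control replicates; the sign pattern
of a reciprocal pair maps onto six interaction types, and per strain
combination three summary measures are formed over all directed non-self
effects among its members:

* interaction score — mean of the +1/0/-1 sign codes (in [-1, 1]),
* mean absolute effect — mean of |GE - 1| (strength, sign-blind),
* proportion of positive effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import StrainCombination
from .simulate import CONTROL_ID

DEFAULT_ALPHA = 0.05
#: |GE - 1| below which an effect counts as neutral when too few
#: replicates exist for a location test.
DEFAULT_FALLBACK_THRESHOLD = 0.05

INTERACTION_TYPES = (
    "mutual_stimulation",
    "one_way_stimulation",
    "no_effect",
    "contrasting",
    "one_way_inhibition",
    "mutual_inhibition",
)


class SupernatantError(ValueError):
    pass


def growth_effect(treatment_values: Sequence[float], control_values: Sequence[float]) -> float:
    """GE = median(treatment) / median(control)."""
    t = np.asarray(treatment_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise SupernatantError("empty replicate set")
    c_med = float(np.median(c))
    if c_med <= 0:
        raise SupernatantError(f"non-positive control median {c_med} (failed control wells?)")
    return float(np.median(t)) / c_med


def classify_effect(
    treatment_values: Sequence[float],
    control_values: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    method: str = "welch",
    fallback_threshold: float = DEFAULT_FALLBACK_THRESHOLD,
) -> int:
    """Sign of a directed effect: +1 stimulation, -1 inhibition, 0 neutral.

    Neutrality is decided by a two-sided location test on the replicate
    values (Welch t-test by default, ``method="mannwhitney"`` for the
    rank-based alternative); a non-significant test at ``alpha`` gives 0,
    otherwise the sign of GE - 1.  With fewer than two replicates in
    either group the classification falls back to the effect-size
    threshold |GE - 1| > ``fallback_threshold``.
    """
    t = np.asarray(treatment_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if t.size == 0 or c.size == 0:
        raise SupernatantError("empty replicate set")
    ge = growth_effect(t, c)
    if t.size < 2 or c.size < 2:
        return int(np.sign(ge - 1.0)) if abs(ge - 1.0) > fallback_threshold else 0
    if method == "welch":
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.ttest_ind(t, c, equal_var=False).pvalue
    elif method == "mannwhitney":
        p = stats.mannwhitneyu(t, c, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(p):  # degenerate (zero-variance) groups
        return int(np.sign(ge - 1.0)) if abs(ge - 1.0) > fallback_threshold else 0
    if p > alpha:
        return 0
    return int(np.sign(ge - 1.0))


def interaction_type(sign_ab: int, sign_ba: int) -> str:
    """Map a reciprocal sign pair to one of the six interaction types.

    Symmetric in its arguments: [+/+] mutual stimulation, [+/0] one-way
    stimulation, [0/0] no effect, [+/-] contrasting, [0/-] one-way
    inhibition, [-/-] mutual inhibition.
    """
    signs = {sign_ab, sign_ba}
    if not signs <= {-1, 0, 1}:
        raise ValueError(f"signs must be in {{-1, 0, 1}}, got {sign_ab}, {sign_ba}")
    if signs == {1}:
        return "mutual_stimulation"
    if signs == {1, 0}:
        return "one_way_stimulation"
    if signs == {0}:
        return "no_effect"
    if signs == {1, -1}:
        return "contrasting"
    if signs == {0, -1}:
        return "one_way_inhibition"
    return "mutual_inhibition"


def effects_from_measurements(
    measurements: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    method: str = "welch",
    fallback_threshold: float = DEFAULT_FALLBACK_THRESHOLD,
    timepoint_h: float = 24.0,
) -> pd.DataFrame:
    """Compute all directed supernatant effects from a measurement table.

    ``measurements`` is the long supernatant table (donor_id, receiver_id,
    condition, treatment, replicate, timepoint_h, od600); rows with donor
    ``CONTROL`` are the per-receiver controls.  Only rows at the requested
    endpoint (24 h by default, 48 h supported) enter.  Returns one row per
    donor x receiver x condition with ge, sign, is_self and the test
    p-value.  The Welch route is vectorised from group statistics.
    """
    df = measurements
    if "timepoint_h" in df.columns:
        df = df[np.isclose(df["timepoint_h"].astype(float), timepoint_h)]
    if df.empty:
        raise SupernatantError(f"no measurements at timepoint {timepoint_h} h")

    is_control = df["donor_id"] == CONTROL_ID
    ctrl = (
        df[is_control]
        .groupby(["receiver_id", "condition"])["od600"]
        .agg(c_median="median", c_mean="mean", c_var="var", c_n="count")
    )
    if (ctrl["c_n"] < 1).any() or ctrl.empty:
        raise SupernatantError("missing control wells")
    treat = (
        df[~is_control]
        .groupby(["donor_id", "receiver_id", "condition"])["od600"]
        .agg(t_median="median", t_mean="mean", t_var="var", t_n="count")
        .reset_index()
    )
    out = treat.join(ctrl, on=["receiver_id", "condition"])
    if out[["c_median"]].isna().any().any():
        raise SupernatantError("treatment rows without matching control group")
    if (out["c_median"] <= 0).any():
        raise SupernatantError("non-positive control median")
    out["ge"] = out["t_median"] / out["c_median"]

    if method == "welch":
        v_t = out["t_var"] / out["t_n"]
        v_c = out["c_var"] / out["c_n"]
        enough = (out["t_n"] >= 2) & (out["c_n"] >= 2)
        denom = np.sqrt(v_t + v_c)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = (out["t_mean"] - out["c_mean"]) / denom
            dof = (v_t + v_c) ** 2 / (
                v_t**2 / (out["t_n"] - 1) + v_c**2 / (out["c_n"] - 1)
            )
        pval = 2.0 * stats.t.sf(np.abs(tstat), dof)
        sign = np.where(pval <= alpha, np.sign(out["ge"] - 1.0), 0.0)
        fb = np.where(np.abs(out["ge"] - 1.0) > fallback_threshold,
                      np.sign(out["ge"] - 1.0), 0.0)
        # threshold fallback when replicates are missing or the test is
        # degenerate (zero within-group variance)
        sign = np.where(enough & np.isfinite(pval), sign, fb)
        out["p_value"] = pval
        out["sign"] = sign.astype(int)
    else:
        signs, pvals = [], []
        grouped_t = df[~is_control].groupby(["donor_id", "receiver_id", "condition"])
        ctrl_vals = {
            k: g["od600"].to_numpy()
            for k, g in df[is_control].groupby(["receiver_id", "condition"])
        }
        for r in out.itertuples(index=False):
            tv = grouped_t.get_group((r.donor_id, r.receiver_id, r.condition))[
                "od600"
            ].to_numpy()
            cv = ctrl_vals[(r.receiver_id, r.condition)]
            signs.append(classify_effect(tv, cv, alpha, method, fallback_threshold))
            pvals.append(np.nan)
        out["sign"] = signs
        out["p_value"] = pvals

    out["is_self"] = out["donor_id"] == out["receiver_id"]
    cols = ["donor_id", "receiver_id", "condition", "ge", "sign", "is_self", "p_value"]
    return out[cols].sort_values(["condition", "donor_id", "receiver_id"]).reset_index(
        drop=True
    )


@dataclass(frozen=True)
class InteractionSummary:
    combination_id: str
    condition: str
    interaction_score: float
    mean_abs_effect: float
    prop_positive: float
    n_directed_effects: int


def summarize_combination(
    effects: pd.DataFrame, combination: StrainCombination, condition: str
) -> InteractionSummary:
    """Summarise all directed non-self effects among a combination's members.

    Requires every ordered donor-receiver pair among the members
    (richness x (richness - 1) directed effects); self-effects are
    excluded from all three measures.
    """
    members = combination.members
    sel = effects[
        (effects["condition"] == condition)
        & effects["donor_id"].isin(members)
        & effects["receiver_id"].isin(members)
        & (effects["donor_id"] != effects["receiver_id"])
    ]
    n_expected = combination.richness * (combination.richness - 1)
    if len(sel) != n_expected:
        raise SupernatantError(
            f"{combination.combination_id}/{condition}: expected {n_expected} "
            f"directed effects, found {len(sel)}"
        )
    if n_expected == 0:
        return InteractionSummary(
            combination.combination_id, condition, 0.0, 0.0, 0.0, 0
        )
    signs = sel["sign"].to_numpy()
    return InteractionSummary(
        combination_id=combination.combination_id,
        condition=condition,
        interaction_score=float(np.mean(signs)),
        mean_abs_effect=float(np.mean(np.abs(sel["ge"].to_numpy() - 1.0))),
        prop_positive=float(np.mean(signs == 1)),
        n_directed_effects=int(n_expected),
    )


def summarize_all(
    effects: pd.DataFrame, combinations: Sequence[StrainCombination]
) -> pd.DataFrame:
    """Interaction summaries for every combination x condition (richness >= 2)."""
    conditions = sorted(effects["condition"].unique())
    nonself = effects[effects["donor_id"] != effects["receiver_id"]]
    lookup: dict[tuple, tuple[float, int]] = {
        (r.donor_id, r.receiver_id, r.condition): (r.ge, r.sign)
        for r in nonself.itertuples(index=False)
    }
    rows = []
    for combo in combinations:
        if combo.richness < 2:
            continue
        members = sorted(combo.members)
        pairs = [(d, r) for d in members for r in members if d != r]
        for cond in conditions:
            try:
                vals = [lookup[(d, r, cond)] for d, r in pairs]
            except KeyError as err:
                raise SupernatantError(
                    f"{combo.combination_id}/{cond}: missing directed effect {err}"
                ) from err
            ge = np.array([v[0] for v in vals], dtype=float)
            signs = np.array([v[1] for v in vals], dtype=float)
            rows.append(
                {
                    "combination_id": combo.combination_id,
                    "community_id": combo.community_id,
                    "condition": cond,
                    "richness": combo.richness,
                    "interaction_score": float(np.mean(signs)),
                    "mean_abs_effect": float(np.mean(np.abs(ge - 1.0))),
                    "prop_positive": float(np.mean(signs == 1)),
                    "n_directed_effects": len(pairs),
                }
            )
    return pd.DataFrame(rows)
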