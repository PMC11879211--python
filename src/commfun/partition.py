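"""Sequential linear-model partitioning of community-functioning variance.

The method splits the variance of a community-level trait across the
2-, 3- and 4-strain combinations of one community into sequential
(Type-I) components:

(i)   strain richness as a continuous covariate (linear diversity
      effect),
(ii)  strain identity, entered as the presence/absence of each strain,
(iii) strain interactions, entered either statistically (richness as a
      categorical factor, capturing non-linear richness effects) or via
      supernatant-based predictors (the interaction score, or the mean
      absolute supernatant effect together with the proportion of
      positive effects).

Each stage's sum of squares is the increment in explained SS as its
column block is appended to the cumulative design; degrees of freedom
are the rank increments, and mean squares SS/df are the effect-size
currency for comparing identity against interaction effects.  On the
balanced full design the identity and interaction stages are orthogonal,
so their mean squares do not depend on the fitting order.

Strain contribution coefficients are obtained by regressing the
stage-(i) residuals on the four presence indicators (no intercept) and
centering them, measuring each strain's effect on functioning relative
to the community average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .design import StrainCombination

VARIANTS = ("nonlinear_richness", "interaction_score", "combined_supernatant")
STAGES = ("linear_richness", "strain_id", "interaction")


class PartitionError(ValueError):
    pass


@dataclass
class PartitionInput:
    """Rows = richness >= 2 cultures of one community under one condition."""

    community_id: str
    condition: str
    response: str  # name of the response column in ``data``
    strain_ids: tuple[str, ...]
    data: pd.DataFrame  # response, richness, presence_<strain>, predictors
    balanced: bool = True

    @property
    def presence_columns(self) -> list[str]:
        return [f"presence_{s}" for s in self.strain_ids]


@dataclass
class StageResult:
    ss: float
    df: int
    mean_square: float


@dataclass
class DecompositionResult:
    community_id: str
    condition: str
    response: str
    variant: str
    stages: dict[str, StageResult]
    strain_coefficients: dict[str, float]
    residual_ss: float
    residual_df: int
    total_ss: float
    n_rows: int
    warnings: list[str] = field(default_factory=list)


def make_partition_input(
    traits: pd.DataFrame,
    combinations: Sequence[StrainCombination],
    community_id: str,
    condition: str,
    response: str = "productivity",
    summaries: pd.DataFrame | None = None,
    transform: str = "none",
) -> PartitionInput:
    """Assemble the design rows for one community x condition.

    ``traits`` is a (replicate-level or aggregated) trait table holding
    ``combination_id, condition`` and the response column;
    ``summaries`` adds the supernatant predictors per combination.
    ``transform`` optionally applies log or sqrt to the response.
    """
    combos = [
        c for c in combinations if c.community_id == community_id and c.richness >= 2
    ]
    if not combos:
        raise PartitionError(f"no richness >= 2 combinations for {community_id}")
    strain_ids = tuple(sorted(set().union(*[c.members for c in combos])))
    members = {c.combination_id: c.members for c in combos}

    df = traits[
        traits["combination_id"].isin(members) & (traits["condition"] == condition)
    ].copy()
    if df.empty:
        raise PartitionError(f"no trait rows for {community_id}/{condition}")
    if response not in df.columns:
        raise PartitionError(f"response column {response!r} missing")
    y = df[response].astype(float)
    if transform == "log":
        if (y <= 0).any():
            raise PartitionError("log transform needs positive response values")
        y = np.log(y)
    elif transform == "sqrt":
        if (y < 0).any():
            raise PartitionError("sqrt transform needs non-negative response values")
        y = np.sqrt(y)
    elif transform != "none":
        raise PartitionError(f"unknown transform {transform!r}")
    df["__response__"] = y
    if not np.isfinite(df["__response__"]).all():
        raise PartitionError("non-finite response values")

    for s in strain_ids:
        df[f"presence_{s}"] = [
            1.0 if s in members[cid] else 0.0 for cid in df["combination_id"]
        ]
    if summaries is not None:
        keys = ["combination_id", "condition", "interaction_score",
                "mean_abs_effect", "prop_positive"]
        df = df.merge(summaries[keys], on=["combination_id", "condition"], how="left")
        if df[["interaction_score", "mean_abs_effect", "prop_positive"]].isna().any().any():
            raise PartitionError("supernatant summaries missing for some combinations")

    n_combos = df["combination_id"].nunique()
    # the full design holds every subset of >= 2 of the community's strains
    full = 2 ** len(strain_ids) - 1 - len(strain_ids)
    counts = df.groupby("combination_id").size()
    balanced = n_combos == full and counts.nunique() == 1
    return PartitionInput(
        community_id=community_id,
        condition=condition,
        response=response,
        strain_ids=strain_ids,
        data=df.reset_index(drop=True),
        balanced=bool(balanced),
    )


def _interaction_block(inp: PartitionInput, variant: str) -> np.ndarray:
    d = inp.data
    if variant == "nonlinear_richness":
        levels = sorted(d["richness"].unique())
        return np.column_stack(
            [(d["richness"] == lv).to_numpy(dtype=float) for lv in levels]
        )
    if variant == "interaction_score":
        return d[["interaction_score"]].to_numpy(dtype=float)
    if variant == "combined_supernatant":
        return d[["mean_abs_effect", "prop_positive"]].to_numpy(dtype=float)
    raise PartitionError(f"unknown variant {variant!r} (one of {VARIANTS})")


def _blocks(inp: PartitionInput, variant: str) -> dict[str, np.ndarray]:
    d = inp.data
    return {
        "linear_richness": d[["richness"]].to_numpy(dtype=float),
        "strain_id": d[inp.presence_columns].to_numpy(dtype=float),
        "interaction": _interaction_block(inp, variant),
    }


def _type1_sums_of_squares(
    y: np.ndarray, blocks: list[tuple[str, np.ndarray]]
) -> tuple[dict[str, StageResult], float, int]:
    """Sequential explained-SS increments over cumulative least squares."""
    n = y.size
    X = np.ones((n, 1))
    rss_prev = float(np.sum((y - y.mean()) ** 2))
    rank_prev = 1
    stages: dict[str, StageResult] = {}
    for name, block in blocks:
        X = np.hstack([X, np.atleast_2d(block)])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ beta) ** 2))
        ss = max(rss_prev - rss, 0.0)
        df = int(rank) - rank_prev
        ms = ss / df if df > 0 else np.nan
        stages[name] = StageResult(ss=ss, df=df, mean_square=ms)
        rss_prev, rank_prev = rss, int(rank)
    return stages, rss_prev, n - rank_prev


def strain_coefficients(inp: PartitionInput) -> dict[str, float]:
    """Centered per-strain contribution coefficients.

    Least-squares fit of the linear-richness-stage residuals on the
    presence indicators (no intercept); centering makes the coefficients
    sum to zero, i.e. contributions relative to the average strain.
    """
    d = inp.data
    y = d["__response__"].to_numpy(dtype=float)
    X1 = np.column_stack([np.ones(y.size), d["richness"].to_numpy(dtype=float)])
    beta1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta1
    P = d[inp.presence_columns].to_numpy(dtype=float)
    if np.linalg.matrix_rank(P) < P.shape[1]:
        raise PartitionError("presence matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(P, resid, rcond=None)
    coef = coef - coef.mean()
    return dict(zip(inp.strain_ids, coef))


def sequential_partition(inp: PartitionInput, variant: str = "nonlinear_richness") -> DecompositionResult:
    """Run the three-stage sequential decomposition for one input."""
    d = inp.data
    y = d["__response__"].to_numpy(dtype=float)
    blocks = _blocks(inp, variant)
    n_combos = d["combination_id"].nunique()
    if n_combos < 4:
        raise PartitionError(f"need >= 4 distinct combinations, got {n_combos}")
    ordered = [(s, blocks[s]) for s in STAGES]
    stages, rss, rdf = _type1_sums_of_squares(y, ordered)
    warnings = []
    if stages["interaction"].df == 0:
        warnings.append(
            f"interaction block adds no rank (constant predictor?); MS undefined"
        )
    if not inp.balanced:
        warnings.append("design is unbalanced; stage SS depend on fitting order")
    total = float(np.sum((y - y.mean()) ** 2))
    return DecompositionResult(
        community_id=inp.community_id,
        condition=inp.condition,
        response=inp.response,
        variant=variant,
        stages=stages,
        strain_coefficients=strain_coefficients(inp),
        residual_ss=rss,
        residual_df=rdf,
        total_ss=total,
        n_rows=int(y.size),
        warnings=warnings,
    )


@dataclass
class OrthogonalityReport:
    ms_id_order1: float
    ms_id_order2: float
    ms_int_order1: float
    ms_int_order2: float
    max_relative_difference: float
    balanced: bool


def orthogonality_check(
    inp: PartitionInput, variant: str = "nonlinear_richness"
) -> OrthogonalityReport:
    """Fit identity and interaction stages in both orders after stage (i).

    On the balanced full design the two mean-square sets coincide
    (orthogonal stages); on unbalanced designs the report carries the
    induced discrepancy.
    """
    d = inp.data
    y = d["__response__"].to_numpy(dtype=float)
    blocks = _blocks(inp, variant)
    s1, *_ = _type1_sums_of_squares(
        y, [("linear_richness", blocks["linear_richness"]),
            ("strain_id", blocks["strain_id"]),
            ("interaction", blocks["interaction"])]
    )
    s2, *_ = _type1_sums_of_squares(
        y, [("linear_richness", blocks["linear_richness"]),
            ("interaction", blocks["interaction"]),
            ("strain_id", blocks["strain_id"])]
    )
    ms = [
        s1["strain_id"].mean_square,
        s2["strain_id"].mean_square,
        s1["interaction"].mean_square,
        s2["interaction"].mean_square,
    ]
    pairs = [(ms[0], ms[1]), (ms[2], ms[3])]
    rel = 0.0
    for a, b in pairs:
        scale = max(abs(a), abs(b), 1e-300)
        rel = max(rel, abs(a - b) / scale) if scale > 1e-290 else rel
    return OrthogonalityReport(
        ms_id_order1=ms[0],
        ms_id_order2=ms[1],
        ms_int_order1=ms[2],
        ms_int_order2=ms[3],
        max_relative_difference=rel,
        balanced=inp.balanced,
    )


def decomposition_frame(results: Sequence[DecompositionResult]) -> pd.DataFrame:
    """Long table: one row per community x condition x variant x stage."""
    rows = []
    for r in results:
        for stage in STAGES:
            s = r.stages[stage]
            rows.append(
                {
                    "community_id": r.community_id,
                    "condition": r.condition,
                    "response": r.response,
                    "variant": r.variant,
                    "stage": stage,
                    "ss": s.ss,
                    "df": s.df,
                    "mean_square": s.mean_square,
                }
            )
        rows.append(
            {
                "community_id": r.community_id,
                "condition": r.condition,
                "response": r.response,
                "variant": r.variant,
                "stage": "residual",
                "ss": r.residual_ss,
                "df": r.residual_df,
                "mean_square": (
                    r.residual_ss / r.residual_df if r.residual_df > 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def coefficients_frame(results: Sequence[DecompositionResult]) -> pd.DataFrame:
    rows = []
    seen = set()
    for r in results:
        key = (r.community_id, r.condition, r.response)
        if key in seen:  # coefficients do not depend on the variant
            continue
        seen.add(key)
        for sid, coef in r.strain_coefficients.items():
            rows.append(
                {
                    "community_id": r.community_id,
                    "condition": r.condition,
                    "response": r.response,
                    "strain_id": sid,
                    "coefficient": coef,
                }
            )
    return pd.DataFrame(rows)


def compare_variants(results: Sequence[DecompositionResult]) -> pd.DataFrame:
    """Mean-square comparison across predictors, per community x condition.

    One row per community x condition x predictor (strain_id,
    linear_richness, and one per interaction variant) with its mean
    square and the log10 ratio of the identity mean square to each
    interaction predictor's mean square.
    """
    rows = []
    by_key: dict[tuple, dict[str, float]] = {}
    for r in results:
        key = (r.community_id, r.condition, r.response)
        entry = by_key.setdefault(key, {})
        entry["strain_id"] = r.stages["strain_id"].mean_square
        entry["linear_richness"] = r.stages["linear_richness"].mean_square
        entry[r.variant] = r.stages["interaction"].mean_square
    for (cid, cond, resp), entry in sorted(by_key.items()):
        ms_id = entry.get("strain_id", np.nan)
        for predictor, ms in sorted(entry.items()):
            ratio = np.nan
            if predictor not in ("strain_id", "linear_richness"):
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = float(np.log10(ms_id / ms)) if ms and ms > 0 else np.nan
            rows.append(
                {
                    "community_id": cid,
                    "condition": cond,
                    "response": resp,
                    "predictor": predictor,
                    "mean_square": ms,
                    "log10_id_over_predictor": ratio,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RegressionSummary:
    slope: float
    stderr: float
    tvalue: float
    pvalue: float
    n: int


def relate_dev_to_score(
    traits: pd.DataFrame, summaries: pd.DataFrame, response: str = "dev_productivity"
) -> RegressionSummary:
    """OLS of DEV on the interaction score, adjusting for condition and richness.

    A fixed-effects stand-in for the full mixed-model analysis: rows are
    combinations x conditions, the reported slope is the interaction-score
    effect.  Standard errors are cluster-robust by community whenever
    several communities are present — DEV rows of one community share
    monoculture references, so their errors are correlated and plain OLS
    standard errors would be anti-conservative.
    """
    df = traits.merge(
        summaries[["combination_id", "condition", "interaction_score"]],
        on=["combination_id", "condition"],
        how="inner",
    ).dropna(subset=[response, "interaction_score"])
    if len(df) < 3:
        raise PartitionError("need >= 3 rows for the DEV ~ score regression")
    if np.isclose(df["interaction_score"].var(), 0.0):
        raise PartitionError("interaction score is constant (degenerate predictor)")
    formula = f"{response} ~ interaction_score + richness"
    if df["condition"].nunique() > 1:
        formula += " + C(condition)"
    model = smf.ols(formula, data=df)
    if "community_id" in df.columns and df["community_id"].nunique() > 1:
        fit = model.fit(
            cov_type="cluster", cov_kwds={"groups": df["community_id"]}, use_t=True
        )
    else:
        fit = model.fit()
    return RegressionSummary(
        slope=float(fit.params["interaction_score"]),
        stderr=float(fit.bse["interaction_score"]),
        tvalue=float(fit.tvalues["interaction_score"]),
        pvalue=float(fit.pvalues["interaction_score"]),
        n=int(fit.nobs),
    )
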