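"""End-to-end analysis of one study: effects → traits → decomposition.

Thin glue over the stage modules so tests, the command-line pipeline and
simulation harnesses run the identical path.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

import numpy as np

from . import design, functioning, partition, simulate, supernatant
from .simulate import SyntheticStudy


@dataclass
class StudyAnalysis:
    effects: pd.DataFrame
    summaries: pd.DataFrame
    traits: functioning.TraitTables
    combinations: list[design.StrainCombination]


def analyze_measurements(
    supernatant_meas: pd.DataFrame,
    competition_meas: pd.DataFrame,
    combinations: list[design.StrainCombination],
    alpha: float = supernatant.DEFAULT_ALPHA,
    aggregate: str = "median",
    endpoint_timepoint_h: float = 24.0,
) -> StudyAnalysis:
    effects = supernatant.effects_from_measurements(
        supernatant_meas, alpha=alpha, timepoint_h=endpoint_timepoint_h
    )
    summaries = supernatant.summarize_all(effects, combinations)
    traits = functioning.build_trait_table(
        competition_meas, combinations, aggregate=aggregate
    )
    return StudyAnalysis(
        effects=effects, summaries=summaries, traits=traits, combinations=combinations
    )


def analyze_study(study: SyntheticStudy, **kwargs) -> StudyAnalysis:
    combos = design.combinations_from_frame(study.combinations)
    return analyze_measurements(study.supernatant, study.competitions, combos, **kwargs)


def decompose_all(
    analysis: StudyAnalysis,
    response: str = "productivity",
    variants: tuple[str, ...] = partition.VARIANTS,
    replicate_level: bool = True,
    transform: str = "none",
) -> list[partition.DecompositionResult]:
    """Sequential decomposition per community x condition x variant."""
    traits = (
        analysis.traits.replicates if replicate_level else analysis.traits.aggregated
    )
    communities = sorted({c.community_id for c in analysis.combinations})
    conditions = sorted(traits["condition"].unique())
    results = []
    for cid in communities:
        for cond in conditions:
            inp = partition.make_partition_input(
                traits,
                analysis.combinations,
                cid,
                cond,
                response=response,
                summaries=analysis.summaries,
                transform=transform,
            )
            for variant in variants:
                results.append(partition.sequential_partition(inp, variant))
    return results


@dataclass
class RegimeResult:
    """Per-community mean squares and coefficient recovery for one regime."""

    mean_squares: pd.DataFrame  # index community, columns strain_id + variants
    coefficient_pairs: pd.DataFrame  # estimated vs true centered identity deviation
    study: SyntheticStudy

    def fraction_identity_dominant(self, variant: str) -> float:
        ms = self.mean_squares
        return float((ms["strain_id"] > ms[variant]).mean())

    def fraction_interaction_dominant(self, variant: str) -> float:
        ms = self.mean_squares
        return float((ms[variant] > ms["strain_id"]).mean())

    def coefficient_recovery_r(self) -> float:
        p = self.coefficient_pairs
        return float(np.corrcoef(p["estimated"], p["true"])[0, 1])


def run_regime(
    identity_sd: float,
    interaction_sd: float,
    n_communities: int,
    seed: int,
    noise_cv: float = 0.05,
    coupling: float = 1.0,
) -> RegimeResult:
    """Simulate + analyse one identity/interaction regime (see
    :func:`commfun.simulate.regime_config`)."""
    study = simulate.generate_study(
        simulate.regime_config(
            identity_sd, interaction_sd, n_communities, seed,
            noise_cv=noise_cv, coupling=coupling,
        )
    )
    analysis = analyze_study(study)
    results = decompose_all(analysis)
    (condition,) = study.config.conditions
    ms_rows: dict[str, dict[str, float]] = {}
    coef_rows = []
    truth = study.truth.monocultures.set_index(["strain_id", "condition"])["identity_dev"]
    seen = set()
    for r in results:
        entry = ms_rows.setdefault(r.community_id, {})
        entry[r.variant] = r.stages["interaction"].mean_square
        entry["strain_id"] = r.stages["strain_id"].mean_square
        if r.community_id not in seen:
            seen.add(r.community_id)
            ids = sorted(r.strain_coefficients)
            true = np.array([truth[(s, condition)] for s in ids])
            true = true - true.mean()
            for s, t in zip(ids, true):
                coef_rows.append(
                    {
                        "community_id": r.community_id,
                        "strain_id": s,
                        "estimated": r.strain_coefficients[s],
                        "true": t,
                    }
                )
    return RegimeResult(
        mean_squares=pd.DataFrame(ms_rows).T.sort_index(),
        coefficient_pairs=pd.DataFrame(coef_rows),
        study=study,
    )
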