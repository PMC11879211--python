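import numpy as np
import pandas as pd
import pytest
from itertools import combinations as subsets

from commfun import design, simulate, workflows


@pytest.fixture(scope="session")
def small_study():
    """Three-community default-condition study, endpoint mode."""
    return simulate.generate_study(simulate.GeneratorConfig(n_communities=3, seed=11))


@pytest.fixture(scope="session")
def small_analysis(small_study):
    return workflows.analyze_study(small_study)


@pytest.fixture(scope="session")
def four_strains():
    return [
        design.Strain(f"S{i}", "C01", "soil", t)
        for i, t in enumerate(design.STRAIN_TYPES, 1)
    ]


def projection_type1_oracle(y, blocks):
    """Independent Type-I oracle via explicit hat matrices.

    Stage SS = y' (H_k - H_{k-1}) y with H the pinv-based projector of
    the cumulative design; df = rank increments.
    """
    n = len(y)
    X = np.ones((n, 1))
    H_prev = X @ np.linalg.pinv(X)
    rank_prev = 1
    out = []
    for block in blocks:
        X = np.hstack([X, np.atleast_2d(block)])
        H = X @ np.linalg.pinv(X)
        ss = float(y @ (H - H_prev) @ y)
        rank = int(np.linalg.matrix_rank(X))
        out.append((ss, rank - rank_prev))
        H_prev, rank_prev = H, rank
    resid = float(y @ (np.eye(n) - H_prev) @ y)
    return out, resid


def residual_fitting_oracle(y, blocks):
    """The residual-refitting route: each stage fits the previous residuals."""
    resid = y - y.mean()
    out = []
    for block in blocks:
        X = np.column_stack([np.ones(len(y)), np.atleast_2d(block)])
        beta, *_ = np.linalg.lstsq(X, resid, rcond=None)
        fitted = X @ beta
        out.append(float(fitted @ fitted - len(y) * fitted.mean() ** 2))
        resid = resid - fitted
    return out, float(resid @ resid)


def random_partition_frame(rng, n_strains=4, replicates=1, drop=0, condition="iron_limited"):
    """A random richness>=2 trait table over one community's design."""
    ids = [f"S{i}" for i in range(1, n_strains + 1)]
    members = [c for k in range(2, n_strains + 1) for c in subsets(ids, k)]
    if drop:  # drop pair combinations so every richness level survives
        members = members[drop:]
    combos = [design.StrainCombination.from_members("C", m) for m in members]
    rows = []
    for c in combos:
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "combination_id": c.combination_id,
                    "condition": condition,
                    "replicate": rep,
                    "richness": c.richness,
                    "productivity": rng.normal(10.0, 2.0),
                }
            )
    summaries = pd.DataFrame(
        {
            "combination_id": [c.combination_id for c in combos],
            "condition": condition,
            "interaction_score": rng.uniform(-1, 1, len(combos)),
            "mean_abs_effect": rng.uniform(0, 0.5, len(combos)),
            "prop_positive": rng.uniform(0, 1, len(combos)),
        }
    )
    return pd.DataFrame(rows), combos, summaries
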