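from itertools import combinations as subsets

import numpy as np
import pandas as pd
import pytest

from commfun import design, partition, simulate, workflows
from commfun.partition import (
    PartitionError,
    make_partition_input,
    orthogonality_check,
    relate_dev_to_score,
    sequential_partition,
)
from conftest import projection_type1_oracle, random_partition_frame, residual_fitting_oracle


def fixture_input(y=None, drop=0, replicates=1, rng=None):
    rng = rng or np.random.default_rng(42)
    traits, combos, summaries = random_partition_frame(
        rng, replicates=replicates, drop=drop
    )
    if y is not None:
        traits["productivity"] = y
    return make_partition_input(
        traits, combos, "C", "iron_limited", summaries=summaries
    )


class TestAgainstROracle:
    """Frozen Type-I sums of squares computed independently with
    R 4.3 ``anova(lm(y ~ rich + pA + pB + pC + pD + factor(rich)))``
    on a fixed 11-combination fixture."""

    R_EXPECTED = {
        "linear_richness": (3.56035588753176, 1),
        "strain_id": (8.26602179578965, 3),  # pA + pB + pC increments
        "interaction": (1.94192658038815, 1),
        "residual": (22.97033277963735, 5),
    }

    def test_matches_r_anova(self):
        strains = ["A", "B", "C", "D"]
        members = [c for k in (2, 3, 4) for c in subsets(strains, k)]
        rng = np.random.default_rng(42)
        y = np.round(10 + rng.normal(0, 2, len(members)), 6)
        combos = [design.StrainCombination.from_members("X", m) for m in members]
        traits = pd.DataFrame(
            {
                "combination_id": [c.combination_id for c in combos],
                "condition": "iron_limited",
                "richness": [c.richness for c in combos],
                "productivity": y,
            }
        )
        inp = make_partition_input(traits, combos, "X", "iron_limited")
        res = sequential_partition(inp, "nonlinear_richness")
        for stage, (ss, df) in self.R_EXPECTED.items():
            if stage == "residual":
                assert res.residual_ss == pytest.approx(ss, rel=1e-10)
                assert res.residual_df == df
            else:
                assert res.stages[stage].ss == pytest.approx(ss, rel=1e-10)
                assert res.stages[stage].df == df


class TestSequentialPartition:
    @pytest.mark.parametrize("variant, int_df", [
        ("nonlinear_richness", 1), ("interaction_score", 1), ("combined_supernatant", 2),
    ])
    def test_stage_dfs(self, variant, int_df):
        res = sequential_partition(fixture_input(replicates=2), variant)
        assert res.stages["linear_richness"].df == 1
        assert res.stages["strain_id"].df == 3  # one presence direction is collinear
        assert res.stages["interaction"].df == int_df

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("drop", [0, 2])
    def test_ss_conservation(self, seed, drop):
        rng = np.random.default_rng(seed)
        inp = fixture_input(drop=drop, replicates=rng.integers(1, 4), rng=rng)
        for variant in partition.VARIANTS:
            res = sequential_partition(inp, variant)
            total = sum(s.ss for s in res.stages.values()) + res.residual_ss
            assert total == pytest.approx(res.total_ss, rel=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_projection_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        inp = fixture_input(replicates=int(rng.integers(1, 3)), rng=rng)
        y = inp.data["__response__"].to_numpy()
        blocks = [
            inp.data[["richness"]].to_numpy(float),
            inp.data[inp.presence_columns].to_numpy(float),
            inp.data[["interaction_score"]].to_numpy(float),
        ]
        oracle, oracle_resid = projection_type1_oracle(y, blocks)
        res = sequential_partition(inp, "interaction_score")
        for (ss, df), stage in zip(oracle, partition.STAGES):
            assert res.stages[stage].ss == pytest.approx(ss, rel=1e-8, abs=1e-10)
            assert res.stages[stage].df == df
        assert res.residual_ss == pytest.approx(oracle_resid, rel=1e-8)

    def test_residual_fitting_route_agrees_on_balanced_design(self):
        """Refitting each stage on the previous stage's residuals (the
        original formulation of the method) reproduces the Type-I
        increments on the balanced design, where the identity and
        nonlinear-richness stages are orthogonal."""
        inp = fixture_input(replicates=2)
        y = inp.data["__response__"].to_numpy()
        blocks = [
            inp.data[["richness"]].to_numpy(float),
            inp.data[inp.presence_columns].to_numpy(float),
            partition._interaction_block(inp, "nonlinear_richness"),
        ]
        seq, _ = residual_fitting_oracle(y, blocks)
        res = sequential_partition(inp, "nonlinear_richness")
        for ss, stage in zip(seq, partition.STAGES):
            assert res.stages[stage].ss == pytest.approx(ss, rel=1e-6, abs=1e-8)

    def test_constant_response_all_zero(self):
        res = sequential_partition(fixture_input(y=np.full(11, 5.0)), "nonlinear_richness")
        for s in res.stages.values():
            assert s.ss == pytest.approx(0.0, abs=1e-18)
        assert res.total_ss == pytest.approx(0.0, abs=1e-18)

    def test_scale_equivariance(self):
        inp1 = fixture_input()
        y = inp1.data["__response__"].to_numpy()
        inp2 = fixture_input(y=y * 7.0)
        r1 = sequential_partition(inp1, "interaction_score")
        r2 = sequential_partition(inp2, "interaction_score")
        for stage in partition.STAGES:
            assert r2.stages[stage].ss == pytest.approx(49.0 * r1.stages[stage].ss, rel=1e-9)
        ratio1 = r1.stages["strain_id"].mean_square / r1.stages["interaction"].mean_square
        ratio2 = r2.stages["strain_id"].mean_square / r2.stages["interaction"].mean_square
        assert ratio1 == pytest.approx(ratio2, rel=1e-9)

    def test_constant_interaction_predictor_flagged(self):
        inp = fixture_input()
        inp.data["interaction_score"] = 0.5
        res = sequential_partition(inp, "interaction_score")
        assert res.stages["interaction"].df == 0
        assert np.isnan(res.stages["interaction"].mean_square)
        assert any("rank" in w for w in res.warnings)

    def test_too_few_combinations(self):
        traits, combos, summ = random_partition_frame(np.random.default_rng(0))
        keep = [c.combination_id for c in combos[:3]]
        inp = make_partition_input(
            traits[traits["combination_id"].isin(keep)], combos[:3], "C",
            "iron_limited", summaries=summ,
        )
        with pytest.raises(PartitionError, match=">= 4"):
            sequential_partition(inp)

    def test_transforms(self):
        traits, combos, _ = random_partition_frame(np.random.default_rng(3))
        inp_log = make_partition_input(
            traits, combos, "C", "iron_limited", transform="log"
        )
        assert np.allclose(
            inp_log.data["__response__"], np.log(inp_log.data["productivity"])
        )
        with pytest.raises(PartitionError):
            traits, combos, _ = random_partition_frame(np.random.default_rng(4))
            traits.loc[0, "productivity"] = -1.0
            make_partition_input(traits, combos, "C", "iron_limited", transform="log")


class TestCoefficients:
    def test_additive_noiseless_recovery(self):
        """With a purely additive noiseless generator the centered strain
        coefficients are proportional to the true identity deviations."""
        study = simulate.generate_study(
            simulate.regime_config(1.0, 0.0, 4, seed=17, noise_cv=0.0)
        )
        analysis = workflows.analyze_study(study)
        results = workflows.decompose_all(analysis, variants=("nonlinear_richness",))
        truth = study.truth.monocultures.set_index(["strain_id", "condition"])["identity_dev"]
        for res in results:
            coefs = res.strain_coefficients
            ids = sorted(coefs)
            est = np.array([coefs[s] for s in ids])
            true = np.array([truth[(s, "iron_rich")] for s in ids])
            true = true - true.mean()
            assert abs(sum(coefs.values())) < 1e-9
            r = np.corrcoef(est, true)[0, 1]
            assert r > 0.999999
            scale = est @ true / (true @ true)
            assert np.allclose(est, scale * true, atol=1e-8)

    def test_rank_deficient_presence_rejected(self):
        traits, combos, summ = random_partition_frame(np.random.default_rng(5))
        keep = [c.combination_id for c in combos if "S1" in c.members and "S2" in c.members]
        sel = traits[traits["combination_id"].isin(keep)]
        inp = make_partition_input(
            sel, [c for c in combos if c.combination_id in keep], "C",
            "iron_limited", summaries=summ,
        )
        with pytest.raises(PartitionError, match="rank"):
            partition.strain_coefficients(inp)


class TestOrthogonality:
    def test_balanced_design_order_invariant(self):
        study = simulate.generate_study(
            simulate.GeneratorConfig(
                n_communities=2, replicates_mix_full=5, seed=13
            )
        )
        analysis = workflows.analyze_study(study)
        inp = make_partition_input(
            analysis.traits.replicates, analysis.combinations, "C01", "iron_limited",
            summaries=analysis.summaries,
        )
        assert inp.balanced
        rep = orthogonality_check(inp, "nonlinear_richness")
        assert rep.max_relative_difference < 1e-8

    def test_dropped_combination_reports_discrepancy(self):
        rng = np.random.default_rng(8)
        traits, combos, summ = random_partition_frame(rng, drop=1)
        inp = make_partition_input(traits, combos, "C", "iron_limited", summaries=summ)
        assert not inp.balanced
        rep = orthogonality_check(inp, "nonlinear_richness")
        assert rep.max_relative_difference > 1e-8

    def test_constant_response_all_zero(self):
        inp = fixture_input(y=np.full(11, 3.0))
        rep = orthogonality_check(inp)
        assert (rep.ms_id_order1, rep.ms_int_order1) == (0.0, 0.0)
        assert (rep.ms_id_order2, rep.ms_int_order2) == (0.0, 0.0)


class TestComparisonAndRegression:
    def test_compare_variants_passthrough(self):
        inp = fixture_input(replicates=2)
        results = [sequential_partition(inp, v) for v in partition.VARIANTS]
        table = partition.compare_variants(results)
        preds = set(table["predictor"])
        assert preds == {"strain_id", "linear_richness", *partition.VARIANTS}
        row = table[table["predictor"] == "interaction_score"].iloc[0]
        ms_id = table[table["predictor"] == "strain_id"]["mean_square"].iloc[0]
        assert row["log10_id_over_predictor"] == pytest.approx(
            np.log10(ms_id / row["mean_square"])
        )

    def test_zero_dev_gives_zero_slope(self):
        study = simulate.generate_study(
            simulate.GeneratorConfig(
                n_communities=3, interaction_sd=0.0, noise_cv=0.0, seed=23
            )
        )
        analysis = workflows.analyze_study(study)
        reg = relate_dev_to_score(analysis.traits.aggregated, analysis.summaries)
        assert reg.slope == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_predictor_rejected(self):
        traits, combos, summ = random_partition_frame(np.random.default_rng(9))
        traits["dev_productivity"] = 1.0
        traits["community_id"] = "C"
        summ["interaction_score"] = 0.0
        with pytest.raises(PartitionError, match="constant"):
            relate_dev_to_score(traits, summ)
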