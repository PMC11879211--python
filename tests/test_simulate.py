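import numpy as np
import pandas as pd
import pytest

from commfun import design, functioning, simulate, supernatant, workflows
from commfun.simulate import GeneratorConfig, SyntheticTruth, generate_study, truth_expected_trait


def degenerate_config(**kw):
    base = dict(
        n_communities=2, identity_sd=0.0, interaction_sd=0.0, noise_cv=0.0, seed=7
    )
    base.update(kw)
    return GeneratorConfig(**base)


class TestConfig:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_communities", 0),
            ("replicates_mix", 0),
            ("noise_cv", -0.1),
            ("identity_sd", -1.0),
            ("coupling", 1.5),
            ("conditions", ("vacuum",)),
            ("timepoints_h", (2.0, 1.0)),
        ],
    )
    def test_invalid_fields_rejected(self, field, value):
        with pytest.raises(simulate.ConfigError):
            GeneratorConfig(**{field: value}).validate()

    def test_dict_round_trip(self):
        cfg = GeneratorConfig(n_communities=3, timepoints_h=(0.0, 1.0, 2.0))
        assert GeneratorConfig.from_dict(cfg.to_dict()) == cfg


class TestGenerateStudy:
    def test_structure(self, small_study):
        s = small_study
        assert len(s.strains) == 3 * 4
        assert s.combinations.groupby("community_id").size().tolist() == [15, 15, 15]
        # every strain of each community appears as donor and receiver
        nonctrl = s.supernatant[s.supernatant["donor_id"] != simulate.CONTROL_ID]
        assert set(nonctrl["donor_id"]) == set(s.strains["strain_id"])

    def test_identical_seed_identical_bytes(self):
        cfg = GeneratorConfig(n_communities=2, seed=123)
        a = generate_study(cfg)
        b = generate_study(GeneratorConfig(n_communities=2, seed=123))
        for name in ("strains", "combinations", "supernatant", "competitions"):
            assert getattr(a, name).to_csv(index=False) == getattr(b, name).to_csv(index=False)

    def test_degenerate_constant_traits(self):
        """No identity spread, no interactions, no noise: under iron-rich
        conditions (shared type baseline) every culture is identical."""
        study = generate_study(degenerate_config())
        rich = study.competitions[study.competitions["condition"] == "iron_rich"]
        assert rich["od600"].nunique() == 1
        combos = design.combinations_from_frame(study.combinations)
        tables = functioning.build_trait_table(study.competitions, combos)
        assert np.allclose(tables.aggregated["dev_productivity"].dropna(), 0.0)
        assert np.allclose(tables.aggregated["dev_pyoverdine"].dropna(), 0.0)

    def test_additive_noiseless_dev_zero(self):
        """interaction_sd = 0, noise_cv = 0: DEV vanishes even with
        identity spread and type-structured baselines."""
        study = generate_study(degenerate_config(identity_sd=1.0))
        combos = design.combinations_from_frame(study.combinations)
        tables = functioning.build_trait_table(study.competitions, combos)
        assert np.allclose(tables.aggregated["dev_productivity"].dropna(), 0.0, atol=1e-10)

    def test_type_baseline_profile(self):
        """Producers outgrow non-producers under iron limitation; all types
        alike when iron is rich; pyoverdine high only for producers under
        limitation."""
        mono = generate_study(degenerate_config()).truth.monocultures
        lim = mono[mono["condition"] == "iron_limited"].set_index("strain_type")
        lim = lim.groupby("strain_type")["productivity_mean"].first()
        assert lim["PVD_PRO"] > lim["NON_PRO"] > lim["NON"]
        assert lim["PVD"] > lim["NON"]
        rich = mono[mono["condition"] == "iron_rich"]
        assert rich["productivity_mean"].nunique() == 1
        pvd = mono[mono["condition"] == "iron_limited"].groupby("strain_type")[
            "pyoverdine_mean"
        ].first()
        assert min(pvd["PVD_PRO"], pvd["PVD"]) > 5 * max(pvd["NON_PRO"], pvd["NON"])

    def test_zero_noise_ge_recovery(self):
        study = generate_study(degenerate_config(identity_sd=0.5, interaction_sd=0.5))
        effects = supernatant.effects_from_measurements(study.supernatant)
        merged = effects.merge(
            study.truth.supernatant,
            on=["donor_id", "receiver_id", "condition"],
            suffixes=("", "_true"),
        )
        assert len(merged) == len(effects)
        assert np.allclose(merged["ge"], merged["ge_true"], rtol=1e-12, atol=0)

    def test_dev_variance_monotone_in_interaction_sd(self):
        variances = []
        for sd in (0.0, 0.5, 1.0, 2.0):
            study = generate_study(
                GeneratorConfig(n_communities=3, interaction_sd=sd, coupling=0.0,
                                noise_cv=0.0, identity_sd=0.0, seed=99)
            )
            combos = design.combinations_from_frame(study.combinations)
            tables = functioning.build_trait_table(study.competitions, combos)
            variances.append(tables.aggregated["dev_productivity"].dropna().var())
        assert all(b >= a - 1e-12 for a, b in zip(variances, variances[1:]))
        assert variances[-1] > variances[0]


class TestTruth:
    def hand_truth(self):
        mono = pd.DataFrame(
            {
                "strain_id": ["A", "B", "C"],
                "community_id": "X",
                "strain_type": ["PVD_PRO", "PVD", "NON"],
                "condition": "iron_limited",
                "identity_dev": 0.0,
                "productivity_mean": [10.0, 20.0, 30.0],
                "pyoverdine_mean": [1.0, 2.0, 3.0],
            }
        )
        pairs = pd.DataFrame(
            {
                "community_id": "X",
                "strain_a": ["A", "A", "B"],
                "strain_b": ["B", "C", "C"],
                "condition": "iron_limited",
                "productivity_contrib": [3.0, 0.0, -3.0],
                "pyoverdine_contrib": [0.0, 0.0, 0.0],
            }
        )
        return SyntheticTruth(mono, pd.DataFrame(), pairs, pd.DataFrame())

    def test_pair_mean_plus_contribution(self):
        truth = self.hand_truth()
        # ({A,B}: (10+20)/2 + 3
        assert truth_expected_trait(truth, {"A", "B"}, "iron_limited") == 18.0
        # singleton: its monoculture mean
        assert truth_expected_trait(truth, {"A"}, "iron_limited") == 10.0
        # cancelling pair contributions: back to the mean of monocultures
        assert truth_expected_trait(truth, {"A", "B", "C"}, "iron_limited") == 20.0

    def test_unknown_strain_or_condition(self):
        truth = self.hand_truth()
        with pytest.raises(KeyError):
            truth_expected_trait(truth, {"A", "Z"}, "iron_limited")
        with pytest.raises(KeyError):
            truth_expected_trait(truth, {"A"}, "iron_rich")

    def test_rederivation_matches_stored_expectation(self, small_study):
        truth = small_study.truth
        combos = design.combinations_from_frame(small_study.combinations)
        for combo in combos:
            for cond in ("iron_limited", "iron_rich"):
                stored = truth.expected.loc[
                    (truth.expected["combination_id"] == combo.combination_id)
                    & (truth.expected["condition"] == cond),
                    "productivity",
                ].iloc[0]
                assert truth_expected_trait(truth, combo.members, cond) == stored

    def test_json_round_trip(self, small_study, tmp_path):
        path = tmp_path / "truth.json"
        small_study.truth.to_json(path)
        back = SyntheticTruth.from_json(path)
        pd.testing.assert_frame_equal(back.expected, small_study.truth.expected)


class TestTimeSeries:
    def test_logistic_integral_matches_endpoint(self):
        cfg = GeneratorConfig(
            n_communities=1, timepoints_h=simulate.default_timepoints(), seed=5,
            conditions=("iron_limited",),
        )
        study = generate_study(cfg)
        combos = design.combinations_from_frame(study.combinations)
        ts_traits = functioning.build_trait_table(study.competitions, combos)
        cfg_ep = GeneratorConfig(n_communities=1, seed=5, conditions=("iron_limited",))
        ep_traits = functioning.build_trait_table(
            generate_study(cfg_ep).competitions, combos
        )
        merged = ts_traits.aggregated.merge(
            ep_traits.aggregated, on=["combination_id", "condition"], suffixes=("_ts", "_ep")
        )
        ratio = merged["productivity_ts"] / merged["productivity_ep"]
        assert np.allclose(ratio, 1.0, rtol=1e-2)  # trapezoid vs analytic integral

    def test_series_integral_is_analytic(self):
        t = np.asarray(simulate.default_timepoints())
        curve = simulate.logistic_series(12.0, t, rate=0.25, midpoint_h=12.0)
        fine = np.linspace(0, 48, 193 * 1000)
        fine_curve = simulate.logistic_series(12.0, fine, rate=0.25, midpoint_h=12.0)
        assert np.trapezoid(fine_curve, fine) == pytest.approx(12.0, rel=1e-6)
        assert np.trapezoid(curve, t) == pytest.approx(12.0, rel=1e-3)
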