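"""Synthetic community experiments with known ground truth.

The generator emulates a combinatorial assembly study with fluorescent
*Pseudomonas*-like strains: per community one strain of each phenotype
class (two pyoverdine producers, two non-producers), grown in monoculture
and in every 2-, 3- and 4-strain mixture under iron-limited and iron-rich
conditions, plus a full supernatant-feeding assay (every donor's sterile
spent medium fed to every community member, against a saline control).

Generative model
----------------
* Strain-type baseline traits per condition follow the canonical
  producer/non-producer phenotype profile: under iron limitation
  pyoverdine producers outgrow non-producers and only producers make
  substantial pyoverdine; under iron-rich conditions all types reach
  similar densities and produce little pyoverdine.
* Each strain gets an identity deviation ``~ Normal(0, identity_sd)``
  (trait units) added to its type baseline, independently per condition.
* Directed supernatant growth effects (GE, ratio to control growth) have
  a positive sign with probability ``positive_interaction_prob[condition]``
  and magnitude ``|GE - 1|`` drawn half-normal.
* The expected trait of a mixture is the mean of its members' monoculture
  means plus the mean over unordered member pairs of a pairwise
  interaction contribution.  The contribution is ``interaction_sd``-scaled
  with a half-normal magnitude; its sign is linked to the pair's directed
  supernatant signs with weight ``coupling`` (1 = fully sign-linked,
  0 = independent).
* An observed replicate is the expected value times
  ``exp(noise_cv * Normal(0, 1))`` (multiplicative log-normal noise:
  plate-reader OD and fluorescence errors scale with signal).
* With ``timepoints_h`` set, growth and pyoverdine time series are
  emitted as logistic curves whose analytic 0-48 h integral equals the
  replicate's endpoint trait value, so the downstream integration stage
  has an exact oracle.

Identical seeds give byte-identical output tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import combinations as _subsets

import numpy as np
import pandas as pd

from . import design
from .design import STRAIN_TYPES, StrainCombination

CONDITIONS = ("iron_limited", "iron_rich")

#: Productivity baselines: 0-48 h integrals of OD600 (OD600*h) for static
#: microplate cultures.  Producers grow best under iron limitation; under
#: iron-rich conditions all types plateau alike.
PRODUCTIVITY_BASELINE = {
    "iron_limited": {"PVD_PRO": 8.0, "PVD": 7.4, "NON_PRO": 6.6, "NON": 4.6},
    "iron_rich": {t: 10.0 for t in STRAIN_TYPES},
}

#: Pyoverdine baselines: 0-48 h integrals of fluorescence (RFU*h).  High
#: only for producers under iron limitation; repressed when iron is rich.
PYOVERDINE_BASELINE = {
    "iron_limited": {"PVD_PRO": 9000.0, "PVD": 8000.0, "NON_PRO": 900.0, "NON": 300.0},
    "iron_rich": {"PVD_PRO": 600.0, "PVD": 550.0, "NON_PRO": 300.0, "NON": 300.0},
}

#: Receiver growth (OD600 at 24 h) in the supernatant assay.
OD24_BASELINE = {
    "iron_limited": {"PVD_PRO": 0.55, "PVD": 0.50, "NON_PRO": 0.45, "NON": 0.33},
    "iron_rich": {t: 0.70 for t in STRAIN_TYPES},
}

CONTROL_ID = "CONTROL"
TREATMENT_BY_CONDITION = {"iron_limited": "SN_limited", "iron_rich": "SN_rich"}


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Parameters of one synthetic study.

    identity_sd and interaction_sd are in productivity units (OD600*h);
    pyoverdine analogues are the same draws scaled by ``pyoverdine_scale``
    (secreted-compound traits are positively linked across strains).
    noise_cv is the log-scale sd of the multiplicative replicate noise.
    """

    n_communities: int = 16
    conditions: tuple[str, ...] = CONDITIONS
    replicates_mono: int = 5
    replicates_mix: int = 5
    replicates_mix_full: int = 6  # the 4-strain culture is replicated more
    replicates_supernatant: int = 4
    replicates_control: int = 3
    identity_sd: float = 1.0
    interaction_sd: float = 1.0
    noise_cv: float = 0.05
    coupling: float = 1.0
    positive_interaction_prob: dict = field(
        default_factory=lambda: {"iron_limited": 0.6, "iron_rich": 0.2}
    )
    self_positive_prob: dict = field(
        default_factory=lambda: {"iron_limited": 0.9, "iron_rich": 0.3}
    )
    ge_magnitude_scale: dict = field(
        default_factory=lambda: {"iron_limited": 0.35, "iron_rich": 0.08}
    )
    pyoverdine_scale: float = 300.0
    timepoints_h: tuple[float, ...] | None = None  # None = endpoint-only tables
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_communities,
            self.replicates_mono,
            self.replicates_mix,
            self.replicates_mix_full,
            self.replicates_supernatant,
            self.replicates_control,
        )
        if any(c < 1 for c in counts):
            raise ConfigError("all counts must be >= 1")
        if not self.conditions or any(c not in CONDITIONS for c in self.conditions):
            raise ConfigError(f"conditions must be drawn from {CONDITIONS}")
        for name in ("positive_interaction_prob", "self_positive_prob"):
            probs = getattr(self, name)
            for c in self.conditions:
                if not 0.0 <= probs[c] <= 1.0:
                    raise ConfigError(f"{name}[{c}] outside [0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.identity_sd < 0 or self.interaction_sd < 0:
            raise ConfigError("effect sds must be >= 0")
        if not 0.0 <= self.coupling <= 1.0:
            raise ConfigError("coupling must lie in [0, 1]")
        if self.timepoints_h is not None:
            t = np.asarray(self.timepoints_h, dtype=float)
            if t.size < 2 or np.any(np.diff(t) <= 0):
                raise ConfigError("timepoints_h must be strictly increasing, >= 2 points")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = list(self.conditions)
        if self.timepoints_h is not None:
            d["timepoints_h"] = list(self.timepoints_h)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "conditions" in d:
            d["conditions"] = tuple(d["conditions"])
        if d.get("timepoints_h") is not None:
            d["timepoints_h"] = tuple(d["timepoints_h"])
        return cls(**d)


def regime_config(
    identity_sd: float,
    interaction_sd: float,
    n_communities: int,
    seed: int,
    noise_cv: float = 0.05,
    coupling: float = 1.0,
) -> GeneratorConfig:
    """Single-condition harness isolating the identity/interaction dials.

    Uses the iron-rich condition, where the four strain types share one
    productivity baseline, so between-strain variance comes only from
    ``identity_sd``; supernatant effects are made strong and balanced in
    sign (equal stimulation/inhibition odds, iron-limited-like magnitudes)
    so the supernatant-based interaction predictors are informative.
    """
    return GeneratorConfig(
        n_communities=n_communities,
        conditions=("iron_rich",),
        positive_interaction_prob={"iron_rich": 0.5},
        self_positive_prob={"iron_rich": 0.5},
        ge_magnitude_scale={"iron_rich": 0.35},
        identity_sd=identity_sd,
        interaction_sd=interaction_sd,
        noise_cv=noise_cv,
        coupling=coupling,
        seed=seed,
    )


def default_timepoints() -> tuple[float, ...]:
    """The plate-reader grid: every 15 min from 0 to 48 h."""
    return tuple(np.arange(0.0, 48.0 + 1e-9, 0.25))


# ---------------------------------------------------------------------------
# logistic time series with analytic integral


def logistic_unit_integral(rate: float, midpoint_h: float, t_end: float) -> float:
    """Integral of 1/(1+exp(-rate*(t-midpoint))) over [0, t_end]."""
    upper = np.logaddexp(0.0, rate * (t_end - midpoint_h))
    lower = np.logaddexp(0.0, -rate * midpoint_h)
    return float((upper - lower) / rate)


def logistic_series(
    target_integral: float, timepoints: np.ndarray, rate: float, midpoint_h: float
) -> np.ndarray:
    """Logistic curve whose analytic 0-T integral equals ``target_integral``."""
    unit = logistic_unit_integral(rate, midpoint_h, float(timepoints[-1]))
    k = target_integral / unit
    return k / (1.0 + np.exp(-rate * (timepoints - midpoint_h)))


LOGISTIC_OD = {"rate": 0.25, "midpoint_h": 12.0}
LOGISTIC_PVD = {"rate": 0.30, "midpoint_h": 16.0}


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SyntheticTruth:
    """Noise-free generative quantities of one synthetic study.

    Sufficient to recompute every expected value without the RNG:
    monoculture means plus pairwise contributions rebuild each mixture's
    expectation, and ``supernatant`` holds the true directed growth
    effects (GE) with their signs.
    """

    monocultures: pd.DataFrame  # strain_id, community_id, strain_type, condition, ...
    supernatant: pd.DataFrame  # donor_id, receiver_id, condition, ge, sign, is_self
    pair_contributions: pd.DataFrame  # strain_a, strain_b, condition, contributions
    expected: pd.DataFrame  # combination_id, condition, productivity, pyoverdine

    def to_json(self, path) -> None:
        payload = {
            name: getattr(self, name).to_dict(orient="list")
            for name in ("monocultures", "supernatant", "pair_contributions", "expected")
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: pd.DataFrame(v) for k, v in payload.items()})


def _truth_lookups(truth: SyntheticTruth, trait: str):
    if trait not in ("productivity", "pyoverdine"):
        raise ValueError(f"unknown trait {trait!r}")
    mono = truth.monocultures.set_index(["strain_id", "condition"])[f"{trait}_mean"]
    pairs = truth.pair_contributions.set_index(["strain_a", "strain_b", "condition"])[
        f"{trait}_contrib"
    ]
    return mono.to_dict(), pairs.to_dict()


def _expected_from_lookups(mono_map, pair_map, members, condition) -> float:
    members = sorted(members)
    try:
        mono_means = np.array([mono_map[(m, condition)] for m in members], dtype=float)
    except KeyError as err:
        raise KeyError(f"{err} not present in truth") from err
    value = float(np.mean(mono_means))
    if len(members) >= 2:
        contribs = np.array(
            [pair_map[(a, b, condition)] for a, b in _subsets(members, 2)], dtype=float
        )
        value = float(np.mean(mono_means) + np.mean(contribs))
    return max(value, 0.0)


def truth_expected_trait(
    truth: SyntheticTruth,
    members,
    condition: str,
    trait: str = "productivity",
) -> float:
    """Noise-free expected trait of a strain set under one condition.

    Mean of the members' monoculture means plus the mean pairwise
    interaction contribution (monocultures have no pair term).
    """
    mono_map, pair_map = _truth_lookups(truth, trait)
    return _expected_from_lookups(mono_map, pair_map, members, condition)


# ---------------------------------------------------------------------------
# study generation


@dataclass
class SyntheticStudy:
    config: GeneratorConfig
    strains: pd.DataFrame
    combinations: pd.DataFrame
    supernatant: pd.DataFrame
    competitions: pd.DataFrame
    truth: SyntheticTruth


def _make_strains(n_communities: int) -> pd.DataFrame:
    rows = []
    n_soil = (n_communities + 1) // 2
    for i in range(n_communities):
        cid = f"C{i + 1:02d}"
        habitat = "soil" if i < n_soil else "freshwater"
        for t in STRAIN_TYPES:
            rows.append(
                {
                    "strain_id": f"{cid}-{t}",
                    "community_id": cid,
                    "habitat": habitat,
                    "strain_type": t,
                }
            )
    return pd.DataFrame(rows)


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate one complete synthetic study (see module docstring)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    strains = _make_strains(config.n_communities)
    conditions = list(config.conditions)

    # --- monoculture means: type baseline + identity deviation -------------
    mono_rows = []
    for r in strains.itertuples(index=False):
        for cond in conditions:
            dev = rng.normal(0.0, config.identity_sd) if config.identity_sd > 0 else 0.0
            prod = max(PRODUCTIVITY_BASELINE[cond][r.strain_type] + dev, 0.1)
            pvd = max(
                PYOVERDINE_BASELINE[cond][r.strain_type] + dev * config.pyoverdine_scale,
                0.0,
            )
            mono_rows.append(
                {
                    "strain_id": r.strain_id,
                    "community_id": r.community_id,
                    "strain_type": r.strain_type,
                    "condition": cond,
                    "identity_dev": dev,
                    "productivity_mean": prod,
                    "pyoverdine_mean": pvd,
                }
            )
    monocultures = pd.DataFrame(mono_rows)

    # --- true directed supernatant effects ---------------------------------
    sn_rows = []
    for cid, grp in strains.groupby("community_id", sort=True):
        ids = sorted(grp["strain_id"])
        for cond in conditions:
            scale = config.ge_magnitude_scale[cond]
            for donor in ids:
                for receiver in ids:
                    is_self = donor == receiver
                    p = (
                        config.self_positive_prob[cond]
                        if is_self
                        else config.positive_interaction_prob[cond]
                    )
                    sgn = 1 if rng.random() < p else -1
                    mag = abs(rng.normal(0.0, scale))
                    ge = max(1.0 + sgn * mag, 0.05)
                    sn_rows.append(
                        {
                            "community_id": cid,
                            "donor_id": donor,
                            "receiver_id": receiver,
                            "condition": cond,
                            "ge": ge,
                            "sign": int(np.sign(ge - 1.0)),
                            "is_self": is_self,
                        }
                    )
    supernatant_truth = pd.DataFrame(sn_rows)
    sn_sign = supernatant_truth.set_index(["donor_id", "receiver_id", "condition"])["sign"]

    # --- pairwise mixture contributions, sign-linked to supernatant signs --
    pair_rows = []
    for cid, grp in strains.groupby("community_id", sort=True):
        ids = sorted(grp["strain_id"])
        for cond in conditions:
            for a, b in _subsets(ids, 2):
                pair_sign = int(np.sign(sn_sign[(a, b, cond)] + sn_sign[(b, a, cond)]))
                indep = rng.normal(0.0, 1.0)
                linked = config.coupling * pair_sign + (1.0 - config.coupling) * indep
                contrib = config.interaction_sd * linked
                pair_rows.append(
                    {
                        "community_id": cid,
                        "strain_a": a,
                        "strain_b": b,
                        "condition": cond,
                        "productivity_contrib": contrib,
                        "pyoverdine_contrib": contrib * config.pyoverdine_scale,
                    }
                )
    pair_contributions = pd.DataFrame(pair_rows)

    # --- combinations and their expected traits ----------------------------
    all_combos: list[StrainCombination] = []
    for cid, grp in strains.groupby("community_id", sort=True):
        comm_strains = design.strains_from_frame(grp, strict=True)
        all_combos.extend(design.enumerate_combinations(comm_strains, 1, 4))
    combinations = design.combinations_to_frame(all_combos)

    truth = SyntheticTruth(
        monocultures=monocultures,
        supernatant=supernatant_truth,
        pair_contributions=pair_contributions,
        expected=pd.DataFrame(),
    )
    prod_maps = _truth_lookups(truth, "productivity")
    pvd_maps = _truth_lookups(truth, "pyoverdine")
    exp_rows = []
    for combo in all_combos:
        for cond in conditions:
            exp_rows.append(
                {
                    "combination_id": combo.combination_id,
                    "community_id": combo.community_id,
                    "condition": cond,
                    "richness": combo.richness,
                    "productivity": _expected_from_lookups(
                        *prod_maps, combo.members, cond
                    ),
                    "pyoverdine": _expected_from_lookups(*pvd_maps, combo.members, cond),
                }
            )
    truth.expected = pd.DataFrame(exp_rows)

    # --- supernatant assay measurements -------------------------------------
    sn_ge = supernatant_truth.set_index(["donor_id", "receiver_id", "condition"])["ge"]
    mono_idx = monocultures.set_index(["strain_id", "condition"])
    meas_rows = []
    for r in strains.sort_values("strain_id").itertuples(index=False):
        for cond in conditions:
            base = OD24_BASELINE[cond][r.strain_type]
            # receiver growth scales with its monoculture productivity
            od24 = base * (
                mono_idx.at[(r.strain_id, cond), "productivity_mean"]
                / PRODUCTIVITY_BASELINE[cond][r.strain_type]
            )
            rfu24 = mono_idx.at[(r.strain_id, cond), "pyoverdine_mean"] / 24.0
            for rep in range(1, config.replicates_control + 1):
                noise = float(np.exp(config.noise_cv * rng.normal()))
                noise_r = float(np.exp(config.noise_cv * rng.normal()))
                meas_rows.append(
                    {
                        "donor_id": CONTROL_ID,
                        "receiver_id": r.strain_id,
                        "condition": cond,
                        "treatment": "SN_control",
                        "replicate": rep,
                        "timepoint_h": 24.0,
                        "od600": od24 * noise,
                        "rfu_pvd": rfu24 * noise_r,
                    }
                )
            donors = sorted(
                strains.loc[strains["community_id"] == r.community_id, "strain_id"]
            )
            for donor in donors:
                ge = sn_ge.at[(donor, r.strain_id, cond)]
                for rep in range(1, config.replicates_supernatant + 1):
                    noise = float(np.exp(config.noise_cv * rng.normal()))
                    noise_r = float(np.exp(config.noise_cv * rng.normal()))
                    meas_rows.append(
                        {
                            "donor_id": donor,
                            "receiver_id": r.strain_id,
                            "condition": cond,
                            "treatment": TREATMENT_BY_CONDITION[cond],
                            "replicate": rep,
                            "timepoint_h": 24.0,
                            "od600": od24 * ge * noise,
                            "rfu_pvd": rfu24 * noise_r,
                        }
                    )
    supernatant_meas = pd.DataFrame(meas_rows)

    # --- competition measurements -------------------------------------------
    exp_idx = truth.expected.set_index(["combination_id", "condition"])
    comp_rows = []
    timepoints = (
        np.asarray(config.timepoints_h, dtype=float)
        if config.timepoints_h is not None
        else None
    )
    for combo in all_combos:
        if combo.richness == 1:
            nrep = config.replicates_mono
        elif combo.richness == 4:
            nrep = config.replicates_mix_full
        else:
            nrep = config.replicates_mix
        for cond in conditions:
            prod_exp = exp_idx.at[(combo.combination_id, cond), "productivity"]
            pvd_exp = exp_idx.at[(combo.combination_id, cond), "pyoverdine"]
            for rep in range(1, nrep + 1):
                m_od = float(np.exp(config.noise_cv * rng.normal()))
                m_pvd = float(np.exp(config.noise_cv * rng.normal()))
                prod_obs = prod_exp * m_od
                pvd_obs = pvd_exp * m_pvd
                if timepoints is None:
                    comp_rows.append(
                        {
                            "combination_id": combo.combination_id,
                            "condition": cond,
                            "replicate": rep,
                            "timepoint_h": np.nan,
                            "od600": prod_obs,
                            "rfu_pvd": pvd_obs,
                        }
                    )
                else:
                    od_t = logistic_series(prod_obs, timepoints, **LOGISTIC_OD)
                    pvd_t = logistic_series(pvd_obs, timepoints, **LOGISTIC_PVD)
                    comp_rows.extend(
                        {
                            "combination_id": combo.combination_id,
                            "condition": cond,
                            "replicate": rep,
                            "timepoint_h": float(t),
                            "od600": float(o),
                            "rfu_pvd": float(p),
                        }
                        for t, o, p in zip(timepoints, od_t, pvd_t)
                    )
    competitions = pd.DataFrame(comp_rows)

    return SyntheticStudy(
        config=config,
        strains=strains,
        combinations=combinations,
        supernatant=supernatant_meas,
        competitions=competitions,
        truth=truth,
    )
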