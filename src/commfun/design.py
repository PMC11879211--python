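"""Strains, communities, and the combinatorial competition design.

A study consists of replicate four-strain communities, each holding one
strain of each phenotype class: a pyoverdine + protease producer
(``PVD_PRO``), a pyoverdine-only producer (``PVD``), a protease-only
producer (``NON_PRO``) and a non-producer (``NON``).  Within every
community all strain combinations of a chosen size range are grown; the
full design has 15 cultures per community (4 monocultures, 6 pairs,
4 triples, 1 four-strain mixture) inoculated substitutively, i.e. at a
constant total starting density.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations as _subsets
from typing import Iterable, Sequence

import pandas as pd

HABITATS = ("soil", "freshwater")
STRAIN_TYPES = ("PVD_PRO", "PVD", "NON_PRO", "NON")

#: Total inoculation density of every culture (OD600 units).
DEFAULT_TOTAL_DENSITY = 0.01

ID_SEPARATOR = "+"


class DesignError(ValueError):
    """Raised when the experimental design is inconsistent."""


@dataclass(frozen=True)
class Strain:
    """One bacterial isolate assigned to a community."""

    strain_id: str
    community_id: str
    habitat: str
    strain_type: str

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise DesignError(f"unknown habitat {self.habitat!r}")
        if self.strain_type not in STRAIN_TYPES:
            raise DesignError(f"unknown strain type {self.strain_type!r}")


def canonical_combination_id(members: Iterable[str]) -> str:
    """Canonical id of a strain set: sorted ids joined with ``+``."""
    ids = sorted(members)
    if len(set(ids)) != len(ids):
        raise DesignError(f"duplicate members in {ids}")
    if not ids:
        raise DesignError("empty member set")
    return ID_SEPARATOR.join(ids)


@dataclass(frozen=True)
class StrainCombination:
    """A set of strains from one community grown together."""

    combination_id: str
    community_id: str
    members: frozenset[str]
    richness: int

    @classmethod
    def from_members(cls, community_id: str, members: Iterable[str]) -> "StrainCombination":
        members = frozenset(members)
        return cls(
            combination_id=canonical_combination_id(members),
            community_id=community_id,
            members=members,
            richness=len(members),
        )

    def __post_init__(self) -> None:
        if self.richness != len(self.members):
            raise DesignError("richness does not match member count")
        if self.combination_id != canonical_combination_id(self.members):
            raise DesignError("combination_id is not canonical")


@dataclass(frozen=True)
class InoculationPlan:
    """Per-strain starting densities of one culture (substitutive design)."""

    combination_id: str
    per_strain_density: dict[str, float]
    total_density: float


def enumerate_combinations(
    strains: Sequence[Strain],
    min_size: int = 1,
    max_size: int | None = None,
) -> list[StrainCombination]:
    """Enumerate all strain combinations of one community.

    Returns every subset with ``min_size <= size <= max_size`` exactly
    once, ordered by richness and then canonical id, so repeated runs
    serialize identically.
    """
    if not strains:
        raise DesignError("no strains given")
    if max_size is None:
        max_size = len(strains)
    if not (1 <= min_size <= max_size <= len(strains)):
        raise DesignError(
            f"invalid size range [{min_size}, {max_size}] for {len(strains)} strains"
        )
    communities = {s.community_id for s in strains}
    if len(communities) != 1:
        raise DesignError(f"strains from multiple communities: {sorted(communities)}")
    (community_id,) = communities
    ids = sorted(s.strain_id for s in strains)
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate strain ids")
    out: list[StrainCombination] = []
    for k in range(min_size, max_size + 1):
        for subset in _subsets(ids, k):
            out.append(StrainCombination.from_members(community_id, subset))
    out.sort(key=lambda c: (c.richness, c.combination_id))
    return out


def substitutive_inoculum(
    combination: StrainCombination, total_density: float = DEFAULT_TOTAL_DENSITY
) -> InoculationPlan:
    """Split the constant total inoculum equally over the members."""
    if not total_density > 0:
        raise DesignError(f"total density must be positive, got {total_density}")
    per = total_density / combination.richness
    return InoculationPlan(
        combination_id=combination.combination_id,
        per_strain_density={sid: per for sid in sorted(combination.members)},
        total_density=total_density,
    )


def validate_design(strains: Sequence[Strain], strict: bool = True) -> None:
    """Check the one-strain-per-type-per-community structure.

    With ``strict`` (the default) every community must contain exactly one
    strain of each of the four types; the variance decomposition's balance
    properties assume this.  ``strict=False`` only enforces unique ids.
    """
    ids = [s.strain_id for s in strains]
    if len(set(ids)) != len(ids):
        raise DesignError("strain ids are not unique")
    if not strict:
        return
    by_comm: dict[str, list[Strain]] = {}
    for s in strains:
        by_comm.setdefault(s.community_id, []).append(s)
    for cid, members in sorted(by_comm.items()):
        types = sorted(s.strain_type for s in members)
        if types != sorted(STRAIN_TYPES):
            raise DesignError(
                f"community {cid} must hold exactly one strain per type, got {types}"
            )
        habitats = {s.habitat for s in members}
        if len(habitats) != 1:
            raise DesignError(f"community {cid} mixes habitats {sorted(habitats)}")


def strains_from_frame(df: pd.DataFrame, strict: bool = True) -> list[Strain]:
    required = {"strain_id", "community_id", "habitat", "strain_type"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"strains table misses columns {sorted(missing)}")
    strains = [
        Strain(
            strain_id=str(r.strain_id),
            community_id=str(r.community_id),
            habitat=str(r.habitat),
            strain_type=str(r.strain_type),
        )
        for r in df.itertuples(index=False)
    ]
    validate_design(strains, strict=strict)
    return strains


def load_strains(path, strict: bool = True) -> list[Strain]:
    """Read strains.csv (strain_id, community_id, habitat, strain_type)."""
    return strains_from_frame(pd.read_csv(path, comment="#"), strict=strict)


def strains_to_frame(strains: Sequence[Strain]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "strain_id": [s.strain_id for s in strains],
            "community_id": [s.community_id for s in strains],
            "habitat": [s.habitat for s in strains],
            "strain_type": [s.strain_type for s in strains],
        }
    )


def combinations_to_frame(combinations: Sequence[StrainCombination]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "combination_id": [c.combination_id for c in combinations],
            "community_id": [c.community_id for c in combinations],
            "members": [ID_SEPARATOR.join(sorted(c.members)) for c in combinations],
            "richness": [c.richness for c in combinations],
        }
    )


def combinations_from_frame(df: pd.DataFrame) -> list[StrainCombination]:
    out = []
    for r in df.itertuples(index=False):
        out.append(
            StrainCombination.from_members(
                str(r.community_id), str(r.members).split(ID_SEPARATOR)
            )
        )
    return out
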