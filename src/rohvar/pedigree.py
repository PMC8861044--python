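"""Pedigree structures for consanguineous families.

Families are built from a small set of canonical union types: an outbred
trio, a first-cousin union (parents share one grandparental couple,
kinship 1/16) and a double-first-cousin union (parents share both
grandparental couples, kinship 1/8).  All ancestors needed for
gene-dropping are materialised as founders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

MALE = "male"
FEMALE = "female"

UNION_KINDS = ("trio", "first_cousin", "double_first_cousin")


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    sex: str
    affected: bool = False
    father_id: Optional[str] = None
    mother_id: Optional[str] = None

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass
class Pedigree:
    members: list[PedigreeMember]
    loops: str = "none"  # none | first_cousin | double_first_cousin

    def __post_init__(self) -> None:
        self._by_id = {m.sample_id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise ValueError("duplicate sample_ids in pedigree")
        self.validate()

    def __getitem__(self, sample_id: str) -> PedigreeMember:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [m.sample_id for m in self.members]

    @property
    def founders(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.is_founder]

    @property
    def affected(self) -> list[PedigreeMember]:
        return [m for m in self.members if m.affected]

    def children_of(self, father_id: str, mother_id: str) -> list[PedigreeMember]:
        return [
            m
            for m in self.members
            if m.father_id == father_id and m.mother_id == mother_id
        ]

    def siblings_of(self, sample_id: str) -> list[PedigreeMember]:
        m = self[sample_id]
        if m.is_founder:
            return []
        return [
            s
            for s in self.children_of(m.father_id, m.mother_id)
            if s.sample_id != sample_id
        ]

    def validate(self) -> None:
        """Check parental references: acyclic, complete, sex-consistent."""
        for m in self.members:
            if (m.father_id is None) != (m.mother_id is None):
                raise ValueError(f"{m.sample_id}: must have two parents or none")
            if m.father_id is not None:
                if m.father_id not in self._by_id or m.mother_id not in self._by_id:
                    raise ValueError(f"{m.sample_id}: parent not in pedigree")
                if self._by_id[m.father_id].sex != MALE:
                    raise ValueError(f"{m.sample_id}: father {m.father_id} not male")
                if self._by_id[m.mother_id].sex != FEMALE:
                    raise ValueError(f"{m.sample_id}: mother {m.mother_id} not female")
        # acyclicity via depth computation (raises on cycles)
        for m in self.members:
            self.depth(m.sample_id)

    def depth(self, sample_id: str, _seen: frozenset = frozenset()) -> int:
        """Generation depth: founders are 0."""
        if sample_id in _seen:
            raise ValueError(f"cycle in pedigree at {sample_id}")
        m = self[sample_id]
        if m.is_founder:
            return 0
        seen = _seen | {sample_id}
        return 1 + max(self.depth(m.father_id, seen), self.depth(m.mother_id, seen))

    # -- relatedness -----------------------------------------------------

    def kinship(self, a: str, b: str) -> float:
        """Kinship coefficient phi(a, b) by the recursive pedigree method."""

        @lru_cache(maxsize=None)
        def phi(x: str, y: str) -> float:
            if self.depth(x) < self.depth(y):
                x, y = y, x
            mx = self[x]
            if x == y:
                if mx.is_founder:
                    return 0.5
                return 0.5 * (1.0 + phi(*sorted((mx.father_id, mx.mother_id))))
            if mx.is_founder:  # both founders, distinct => unrelated
                return 0.0
            return 0.5 * (
                phi(*sorted((mx.father_id, y))) + phi(*sorted((mx.mother_id, y)))
            )

        return phi(*sorted((a, b)))

    def inbreeding(self, sample_id: str) -> float:
        """Expected inbreeding coefficient F = kinship of the parents."""
        m = self[sample_id]
        if m.is_founder:
            return 0.0
        return self.kinship(m.father_id, m.mother_id)


def build_pedigree(
    kind: str,
    n_children: int = 1,
    seed: int | None = None,
    family_id: str = "F1",
    child_sexes: Optional[Iterable[str]] = None,
) -> Pedigree:
    """Construct a family of the given consanguinity kind.

    ``kind`` is one of ``trio`` (unrelated parents), ``first_cousin``
    (parents share one grandparental couple; offspring F = 1/16) or
    ``double_first_cousin`` (parents share both grandparental couples;
    offspring F = 1/8).  ``child_sexes`` defaults to male for the first
    child and alternating thereafter.
    """
    if kind not in UNION_KINDS:
        raise ValueError(f"unknown pedigree kind {kind!r}; expected one of {UNION_KINDS}")
    if n_children < 1:
        raise ValueError("n_children must be >= 1")
    p = family_id
    members: list[PedigreeMember] = []

    def founder(tag: str, sex: str) -> str:
        sid = f"{p}_{tag}"
        members.append(PedigreeMember(sid, sex))
        return sid

    def child(tag: str, sex: str, fa: str, mo: str, affected: bool = False) -> str:
        sid = f"{p}_{tag}"
        members.append(PedigreeMember(sid, sex, affected, fa, mo))
        return sid

    if kind == "trio":
        fa = founder("fa", MALE)
        mo = founder("mo", FEMALE)
        loops = "none"
    elif kind == "first_cousin":
        # one shared grandparental couple; A and B are full siblings
        g1 = founder("g1", MALE)
        g2 = founder("g2", FEMALE)
        sa = founder("sa", FEMALE)  # married into the family
        sb = founder("sb", MALE)
        a = child("a", MALE, g1, g2)
        b = child("b", FEMALE, g1, g2)
        fa = child("fa", MALE, a, sa)
        mo = child("mo", FEMALE, sb, b)
        loops = "first_cousin"
    else:  # double_first_cousin
        g1m = founder("g1m", MALE)
        g1f = founder("g1f", FEMALE)
        g2m = founder("g2m", MALE)
        g2f = founder("g2f", FEMALE)
        a1 = child("a1", MALE, g1m, g1f)
        a2 = child("a2", MALE, g1m, g1f)
        b1 = child("b1", FEMALE, g2m, g2f)
        b2 = child("b2", FEMALE, g2m, g2f)
        fa = child("fa", MALE, a1, b1)
        mo = child("mo", FEMALE, a2, b2)
        loops = "double_first_cousin"

    sexes = list(child_sexes) if child_sexes is not None else []
    for i in range(n_children):
        sex = sexes[i] if i < len(sexes) else (MALE if i % 2 == 0 else FEMALE)
        child(f"c{i + 1}", sex, fa, mo, affected=True)

    return Pedigree(members, loops=loops)


# -- pedigree TSV I/O (sample, father, mother, sex, affected) ------------

PED_COLUMNS = ["sample_id", "father_id", "mother_id", "sex", "affected"]


def write_pedigree_tsv(pedigree: Pedigree, path: str | Path) -> None:
    rows = [
        {
            "sample_id": m.sample_id,
            "father_id": m.father_id or "0",
            "mother_id": m.mother_id or "0",
            "sex": m.sex,
            "affected": int(m.affected),
        }
        for m in pedigree.members
    ]
    pd.DataFrame(rows, columns=PED_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path: str | Path, loops: str = "none") -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str)
    members = []
    for _, r in df.iterrows():
        members.append(
            PedigreeMember(
                sample_id=r["sample_id"],
                sex=r["sex"],
                affected=bool(int(r["affected"])),
                father_id=None if r["father_id"] in ("0", "", None) else r["father_id"],
                mother_id=None if r["mother_id"] in ("0", "", None) else r["mother_id"],
            )
        )
    return Pedigree(members, loops=loops)
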