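"""Nuclear-family pedigree container used by the co-segregation check
and the pedigree simulator.

Carrier status is a trichotomy — ``carrier`` / ``non-carrier`` /
``unknown`` — because in practice only a subset of relatives can be
genotyped for a candidate allele.
"""
from __future__ import annotations

from dataclasses import dataclass, field

CARRIER_STATES = ("carrier", "non-carrier", "unknown")


@dataclass
class PedigreeMember:
    member_id: str
    father: str | None
    mother: str | None
    sex: str  # "M" / "F"
    diagnosis: str | None  # None = unknown / unphenotyped
    carrier: str = "unknown"
    genotype: int | None = None  # minor-allele count, when simulated/known

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex!r}")
        if self.carrier not in CARRIER_STATES:
            raise ValueError(f"carrier must be one of {CARRIER_STATES}")
        if self.genotype is not None and self.genotype not in (0, 1, 2):
            raise ValueError("genotype must be 0, 1 or 2")


@dataclass
class Pedigree:
    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("member IDs must be unique")
        known = set(ids)
        for m in self.members:
            for parent in (m.father, m.mother):
                if parent is not None and parent not in known:
                    raise ValueError(f"{m.member_id}: unknown parent {parent!r}")

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def founders(self) -> list:
        return [m for m in self.members if m.father is None and m.mother is None]

    def children(self) -> list:
        return [m for m in self.members if m.father is not None or m.mother is not None]
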