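"""Unique/shared ASV accounting across depth groups and islands.

Intersection counts use UpSet semantics: each ASV falls in exactly one cell,
the exact combination of groups it occurs in (≥1 read in ≥1 sample of the
group). Percentages are reported against a declared denominator — the total
ASV count of the dataset under analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import pandas as pd

from .assign import AssignmentTable
from .diversity import TaxonProfile, taxon_profile
from .io import CountMatrix, SampleMetadata


@dataclass
class GroupPresence:
    """Per-ASV membership: the subset of groups where the ASV occurs."""

    groups: list[str]
    membership: dict[str, frozenset[str]]

    def per_group(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {g: set() for g in self.groups}
        for asv, mem in self.membership.items():
            for g in mem:
                out[g].add(asv)
        return out

    def unique_to(self, group: str) -> set[str]:
        return {a for a, mem in self.membership.items() if mem == frozenset({group})}

    def unique_any(self) -> set[str]:
        return {a for a, mem in self.membership.items() if len(mem) == 1}

    def shared_by_all(self) -> set[str]:
        everything = frozenset(self.groups)
        return {a for a, mem in self.membership.items() if mem == everything}


def group_presence(cm: CountMatrix, meta: SampleMetadata, key: str,
                   grouping: Mapping | None = None) -> GroupPresence:
    """Assign each ASV to the set of groups it occurs in.

    ``key`` is the metadata column (``depth_m`` or ``island``); ``grouping``
    optionally maps its values to group labels (e.g. pooling 300 m and 500 m
    into one depth group). Every sample must map to exactly one group.
    """
    env = meta.environmental()
    group_of: dict[str, str] = {}
    for sid in cm.sample_ids:
        if sid not in env.index:
            raise ValueError(f"sample {sid!r} missing from environmental metadata")
        value = env.loc[sid, key]
        if grouping is not None:
            if value not in grouping:
                raise ValueError(f"sample {sid!r}: no group for {key}={value!r}")
            group_of[sid] = str(grouping[value])
        else:
            group_of[sid] = str(value)
    groups = sorted(set(group_of.values()))
    presence = cm.presence()
    membership: dict[str, frozenset[str]] = {}
    for asv in cm.asv_ids:
        present = presence[asv]
        mem = frozenset(group_of[s] for s in presence.index[present > 0])
        if not mem:
            warnings.warn(f"ASV {asv!r} has zero reads everywhere; excluded")
            continue
        membership[asv] = mem
    return GroupPresence(groups=groups, membership=membership)


@dataclass
class IntersectionReport:
    """Exact-combination ASV counts with percentage summaries."""

    groups: list[str]
    combination_counts: dict[frozenset, int]
    group_totals: dict[str, int]
    unique_counts: dict[str, int]
    shared_all_count: int
    denominator: int

    @property
    def total_asvs(self) -> int:
        return sum(self.combination_counts.values())

    @property
    def unique_total(self) -> int:
        return sum(self.unique_counts.values())

    def pct(self, count: int) -> float:
        return 100.0 * count / self.denominator

    def pct_rounded(self, count: int) -> int:
        return int(Decimal(repr(self.pct(count))).quantize(Decimal(1), rounding=ROUND_HALF_UP))

    @property
    def unique_pct(self) -> int:
        return self.pct_rounded(self.unique_total)

    @property
    def shared_all_pct(self) -> int:
        return self.pct_rounded(self.shared_all_count)

    def to_frame(self) -> pd.DataFrame:
        rows = [("&".join(sorted(comb)), len(comb), count, self.pct(count), self.pct_rounded(count))
                for comb, count in sorted(self.combination_counts.items(),
                                          key=lambda kv: (-kv[1], sorted(kv[0])))]
        return pd.DataFrame(rows, columns=["combination", "degree", "asv_count",
                                           "pct_raw", "pct"])


def intersections(gp: GroupPresence, denominator: int | None = None) -> IntersectionReport:
    """Exact group-combination counts (UpSet semantics, not cumulative)."""
    total = len(gp.membership)
    if denominator is None:
        denominator = total
    if denominator < total:
        raise ValueError(f"denominator {denominator} smaller than the {total} ASVs counted")
    combos: dict[frozenset, int] = {}
    for mem in gp.membership.values():
        combos[mem] = combos.get(mem, 0) + 1
    per_group = gp.per_group()
    return IntersectionReport(
        groups=gp.groups,
        combination_counts=combos,
        group_totals={g: len(a) for g, a in per_group.items()},
        unique_counts={g: len(gp.unique_to(g)) for g in gp.groups},
        shared_all_count=len(gp.shared_by_all()),
        denominator=denominator,
    )


def unique_shared_taxa(gp: GroupPresence, assign: AssignmentTable,
                       which: str, min_prop: float = 0.02) -> TaxonProfile:
    """Division profile of the ASVs unique to single groups or shared by all."""
    if which == "unique":
        subset = gp.unique_any()
    elif which == "shared_all":
        subset = gp.shared_by_all()
    else:
        raise ValueError(f"which must be 'unique' or 'shared_all', got {which!r}")
    if not subset:
        raise ValueError(f"the {which} ASV set is empty")
    return taxon_profile(sorted(subset), assign, min_prop=min_prop, group=which)
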