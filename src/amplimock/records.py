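"""Sequence records and PR2-style taxonomy lineages.

The reference database, the mock-community references and the denoised ASVs
are all plain nucleotide sequences; references additionally carry an
eight-rank lineage string (kingdom;supergroup;division;class;order;family;
genus;species, the PR2 convention). "Division" — the third rank — is the
level at which community composition profiles are summarised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

N_RANKS = 8
#: placeholder written into lineage positions the source string did not provide
RANK_PLACEHOLDER = "unassigned"
#: 1-based position of the PR2 "division" rank
DIVISION_POSITION = 3

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class TaxonomyLineage:
    """An eight-rank PR2-style lineage."""

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != N_RANKS:
            raise ValueError(f"lineage must have {N_RANKS} ranks, got {len(self.ranks)}")

    @property
    def division(self) -> str:
        return self.ranks[DIVISION_POSITION - 1]

    def __str__(self) -> str:
        return ";".join(self.ranks)


def parse_lineage(s: str) -> TaxonomyLineage:
    """Parse a ``;``-separated PR2 lineage string.

    Strings with fewer than eight ranks are right-padded with
    :data:`RANK_PLACEHOLDER`; strings with more are rejected.
    """
    if not s or not s.strip():
        raise ValueError("empty lineage string")
    ranks = [r.strip() for r in s.rstrip(";").split(";")]
    if len(ranks) > N_RANKS:
        raise ValueError(f"lineage has {len(ranks)} ranks, at most {N_RANKS} allowed: {s!r}")
    if any(not r for r in ranks):
        raise ValueError(f"lineage contains an empty rank: {s!r}")
    ranks += [RANK_PLACEHOLDER] * (N_RANKS - len(ranks))
    return TaxonomyLineage(tuple(ranks))


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Upper-case a nucleotide string and map U to T.

    The whole pipeline operates on a single DNA alphabet {A,C,G,T,N}; RNA
    input (U) is accepted and folded into it at read time.
    """
    if not seq:
        raise ValueError(f"empty {context}")
    norm = seq.upper().replace("U", "T")
    bad = set(norm) - _VALID_BASES
    if bad:
        raise ValueError(f"invalid characters {sorted(bad)} in {context}")
    return norm


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence with an optional lineage."""

    id: str
    seq: str
    lineage: TaxonomyLineage | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty whitespace-free token: {self.id!r}")
        object.__setattr__(self, "seq", normalize_sequence(self.seq, context=f"sequence of {self.id!r}"))
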