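"""Taxonomic assignment of ASVs by best-hit global alignment.

Each ASV is aligned against every reference sequence; the best hit (highest
percent identity, ties broken by the lexicographically smallest reference id)
is kept only if its identity is strictly above ``min_identity`` (80% by
default). Assigned ASVs inherit the reference lineage and a functional class
derived from the division; the downstream analysis keeps heterotrophic
protists only, discarding metazoans, fungi, streptophytes, exclusively
phototrophic taxa and everything that could not be assigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from .align import global_align
from .io import CountMatrix
from .records import SequenceRecord, TaxonomyLineage

DEFAULT_MIN_IDENTITY = 80.0

FUNCTIONAL_CLASSES = ("heterotroph", "metazoa", "fungi", "streptophyte", "phototroph", "unassigned")

#: default division → functional-class map; anything not listed is a heterotroph.
#: "Exclusively phototrophic" divisions are configuration — no canonical list exists.
DEFAULT_EXCLUDED_DIVISIONS: Mapping[str, str] = {
    "Metazoa": "metazoa",
    "Fungi": "fungi",
    "Streptophyta": "streptophyte",
    "Chlorophyta": "phototroph",
    "Rhodophyta": "phototroph",
    "Haptophyta": "phototroph",
    "Cryptophyta": "phototroph",
}


def classify_functional(lineage: TaxonomyLineage | None,
                        excluded_divisions: Mapping[str, str] = DEFAULT_EXCLUDED_DIVISIONS) -> str:
    if lineage is None:
        return "unassigned"
    return excluded_divisions.get(lineage.division, "heterotroph")


@dataclass
class AssignmentTable:
    """Best-hit assignment per ASV: reference, identity, lineage, functional class."""

    table: pd.DataFrame  # index: asv id; columns: best_ref_id, identity_pct, lineage, functional_class

    def __post_init__(self) -> None:
        need = {"best_ref_id", "identity_pct", "lineage", "functional_class"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValueError(f"assignment table missing columns {sorted(missing)}")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.table.index)

    def identity_of(self, asv_id: str) -> float:
        return float(self.table.loc[asv_id, "identity_pct"])

    def division_of(self, asv_id: str) -> str | None:
        lin = self.table.loc[asv_id, "lineage"]
        return lin.division if isinstance(lin, TaxonomyLineage) else None

    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["best_ref_id"].notna()]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["lineage"] = out["lineage"].map(lambda l: str(l) if isinstance(l, TaxonomyLineage) else "")
        return out


class TaxonomicAssigner(BaseEstimator):
    """Best-hit global-alignment assigner with a strict identity cutoff.

    Parameters
    ----------
    min_identity:
        Percent identity an ASV must strictly exceed to be assigned (default 80).
    excluded_divisions:
        Division → functional-class map defining the non-heterotroph groups.

    Attributes
    ----------
    references_:
        The fitted reference records, sorted by id (the tie-break order).
    """

    def __init__(self, min_identity: float = DEFAULT_MIN_IDENTITY,
                 excluded_divisions: Mapping[str, str] | None = None):
        self.min_identity = min_identity
        self.excluded_divisions = excluded_divisions

    def fit(self, references: Sequence[SequenceRecord], y=None) -> "TaxonomicAssigner":
        refs = list(references)
        if not refs:
            raise ValueError("reference database is empty")
        for r in refs:
            if r.lineage is None:
                raise ValueError(f"reference {r.id!r} has no lineage")
        self.references_ = sorted(refs, key=lambda r: r.id)
        return self

    def predict(self, queries: Sequence[SequenceRecord]) -> AssignmentTable:
        """Assign every query; returns the per-ASV assignment table."""
        if not hasattr(self, "references_"):
            raise ValueError("TaxonomicAssigner is not fitted")
        excl = self.excluded_divisions if self.excluded_divisions is not None else DEFAULT_EXCLUDED_DIVISIONS
        rows = []
        for q in queries:
            best_ref: SequenceRecord | None = None
            best_matches, best_len = -1, 1  # identity as exact rational matches/len
            for ref in self.references_:  # sorted by id: first strict improvement wins ties
                aln = global_align(q.seq, ref.seq)
                matches = aln.aln_len - aln.edits
                # exact rational comparison: matches/aln_len > best_matches/best_len
                if matches * best_len > best_matches * aln.aln_len:
                    best_matches, best_len = matches, aln.aln_len
                    best_ref = ref
            best_identity = 100.0 * best_matches / best_len
            # strict cutoff, decided exactly: 100·matches > min_identity·aln_len
            if 100.0 * best_matches > self.min_identity * best_len:
                lineage = best_ref.lineage
                rows.append((q.id, best_ref.id, best_identity, lineage, classify_functional(lineage, excl)))
            else:
                rows.append((q.id, None, best_identity, None, "unassigned"))
        df = pd.DataFrame(rows, columns=["asv", "best_ref_id", "identity_pct", "lineage", "functional_class"])
        return AssignmentTable(df.set_index("asv"))

    def fit_predict(self, references: Sequence[SequenceRecord],
                    queries: Sequence[SequenceRecord]) -> AssignmentTable:
        return self.fit(references).predict(queries)


def assign_all(queries: Sequence[SequenceRecord], refs: Sequence[SequenceRecord],
               min_identity: float = DEFAULT_MIN_IDENTITY,
               excluded_divisions: Mapping[str, str] | None = None) -> AssignmentTable:
    """Assign all queries against the reference set (functional wrapper)."""
    return TaxonomicAssigner(min_identity, excluded_divisions).fit(refs).predict(queries)


def filter_functional(assign: AssignmentTable) -> set[str]:
    """ASV ids that are assigned and heterotrophic — the analysis fraction."""
    t = assign.table
    keep = t["best_ref_id"].notna() & (t["functional_class"] == "heterotroph")
    return set(t.index[keep])


def find_genotype(asv_seqs: Iterable[SequenceRecord], counts: CountMatrix,
                  target: SequenceRecord) -> dict[str, int]:
    """Per-sample read totals of ASVs 100% identical to a cultivated strain.

    Used to rediscover sequenced culture genotypes in the environmental
    dataset; only exact (identity = 100%) matches count, and counts of
    distinct ASV ids with identical sequence are summed.
    """
    hits = [r.id for r in asv_seqs
            if r.id in counts.counts.columns and global_align(r.seq, target.seq).edits == 0]
    if not hits:
        return {}
    totals = counts.counts[hits].sum(axis=1)
    return {s: int(v) for s, v in totals.items() if v > 0}
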