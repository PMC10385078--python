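"""Global pairwise alignment and percent identity.

Identity is computed from an end-to-end (Needleman–Wunsch) alignment under
unit costs — match 0, mismatch 1, gap 1 — as

    identity% = 100 * (alignment columns − edits) / alignment columns,

where *edits* is the minimum global edit distance and the column count is
taken from one optimal alignment path. Alignment is delegated to edlib.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib

_CIGAR_RUN = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentResult:
    """Edit distance, alignment length and percent identity of a global alignment."""

    edits: int
    aln_len: int

    @property
    def identity_pct(self) -> float:
        return 100.0 * (self.aln_len - self.edits) / self.aln_len


def global_align(a: str, b: str) -> AlignmentResult:
    """Globally align two nucleotide strings under unit edit costs.

    The edit distance is unique, but equally optimal alignments can differ in
    column count (a substitution column versus an insertion/deletion pair),
    which moves the identity by a fraction of a percent. The aligner's path
    choice is deterministic for a given input order, so inputs are
    canonically ordered first — this makes the result symmetric in a and b.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    if b < a:
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path")
    edits = res["editDistance"]
    aln_len = sum(int(n) for n, _ in _CIGAR_RUN.findall(res["cigar"]))
    return AlignmentResult(edits=edits, aln_len=aln_len)


def edit_distance(a: str, b: str) -> int:
    """Minimum global (Levenshtein) edit distance; no alignment path computed."""
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return int(edlib.align(a, b, mode="NW", task="distance")["editDistance"])


def identity_pct(a: str, b: str) -> float:
    return global_align(a, b).identity_pct
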