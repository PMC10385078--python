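"""Mock-community threshold calibration and dataset partitioning.

Each sequencing library carries a mock sample — a mixture of nine known
protist species — whose denoised output calibrates two per-library
read-proportion thresholds:

* the **lenient** threshold: the read proportion of the mock ASV with the
  smallest read count still assigned to one of the expected species (allowing
  one base mismatch). Environmental samples on the same lane keep an ASV iff
  its within-sample proportion is **≥** this value, so the defining ASV would
  itself survive.
* the **strict** threshold: the largest read proportion among mock ASVs that
  are *not* one of the expected (distance-0) ASVs — the smallest cutoff that,
  applied with keep-iff-**>** semantics, leaves exactly the expected ASVs.
  It is infeasible when some unexpected ASV outreads an expected one.

Environmental tables are then partitioned into a *main* dataset (lenient
filtering), a *strict* dataset, and a *low-abundance* dataset holding the
cells the lenient filter removed, restricted to ASVs with >98% identity to a
reference sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .align import edit_distance
from .assign import AssignmentTable
from .io import CountMatrix, SampleMetadata
from .records import SequenceRecord

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 1
DEFAULT_LOW_IDENTITY_MIN = 98.0


@dataclass
class MockMatch:
    """Per-ASV matching of one mock sample against the expected species.

    ``table`` is indexed by ASV id with columns ``matched_species`` (expected
    species id or None), ``edit_distance``, ``reads`` and ``proportion``
    (reads over the mock sample's total).
    """

    table: pd.DataFrame
    total_reads: int
    n_expected: int
    max_mismatch: int = DEFAULT_MAX_MISMATCH

    @property
    def matched(self) -> pd.DataFrame:
        return self.table[self.table["matched_species"].notna()]

    @property
    def unmatched(self) -> pd.DataFrame:
        return self.table[self.table["matched_species"].isna()]


def match_mock(mock_counts: CountMatrix, mock_seqs: Sequence[SequenceRecord],
               expected: Sequence[SequenceRecord],
               max_mismatch: int = DEFAULT_MAX_MISMATCH) -> MockMatch:
    """Match every ASV of a one-sample mock table to its closest expected species.

    An ASV is matched iff its minimum edit distance to any expected species is
    ``≤ max_mismatch`` (1 by default); among equally distant species the
    lexicographically smallest species id wins.
    """
    if len(mock_counts.sample_ids) != 1:
        raise ValueError(f"mock table must contain exactly one sample, got {len(mock_counts.sample_ids)}")
    seq_by_id = {r.id: r.seq for r in mock_seqs}
    missing = [a for a in mock_counts.asv_ids if a not in seq_by_id]
    if missing:
        raise ValueError(f"mock ASVs without sequences: {missing[:5]}")
    row = mock_counts.counts.iloc[0]
    total = int(row.sum())
    if total == 0:
        raise ValueError("mock sample has zero reads")
    expected_sorted = sorted(expected, key=lambda r: r.id)
    rows = []
    for asv in mock_counts.asv_ids:
        best_sp, best_d = None, None
        for sp in expected_sorted:
            d = edit_distance(seq_by_id[asv], sp.seq)
            if best_d is None or d < best_d:
                best_sp, best_d = sp.id, d
        matched = best_sp if best_d <= max_mismatch else None
        rows.append((asv, matched, best_d, int(row[asv]), row[asv] / total))
    df = pd.DataFrame(rows, columns=["asv", "matched_species", "edit_distance", "reads", "proportion"])
    return MockMatch(df.set_index("asv"), total_reads=total,
                     n_expected=len(expected_sorted), max_mismatch=max_mismatch)


def lenient_threshold(match: MockMatch) -> float:
    """Proportion of the matched mock ASV with the smallest read count."""
    matched = match.matched
    matched = matched[matched["reads"] > 0]
    if matched.empty:
        raise ValueError("mock failed: no ASV matched an expected species")
    return float(matched["reads"].min() / match.total_reads)


def strict_threshold(match: MockMatch) -> tuple[float, bool]:
    """Exclusive proportion bound leaving only the expected (distance-0) ASVs.

    Returns ``(t_strict, feasible)``: the largest proportion among non-expected
    ASVs (0 if there are none), and whether filtering the mock at that bound
    with keep-iff-> semantics yields exactly the expected set. One-mismatch
    variants count as *assigned* for the lenient rule but are not *expected*
    here — the strict cutoff must remove them too.
    """
    t = match.table
    zero = t[(t["edit_distance"] == 0) & (t["reads"] > 0)]
    n_expected_species = zero["matched_species"].nunique()
    if n_expected_species < match.n_expected:
        raise ValueError(
            f"mock incomplete: only {n_expected_species} of {match.n_expected} species "
            "have an exact-sequence ASV"
        )
    expected_asvs = set(zero.index)
    non_expected = t.loc[[a for a in t.index if a not in expected_asvs]]
    non_expected = non_expected[non_expected["reads"] > 0]
    t_strict = float(non_expected["proportion"].max()) if not non_expected.empty else 0.0
    feasible = bool((zero["proportion"] > t_strict).all())
    return t_strict, feasible


@dataclass
class ThresholdSet:
    """Per-library lenient and strict thresholds with provenance diagnostics."""

    per_library: pd.DataFrame  # index: library_id; columns: t_lenient, t_strict, feasible_strict
    diagnostics: dict = field(default_factory=dict)

    def t_lenient(self, library_id: str) -> float:
        return float(self.per_library.loc[library_id, "t_lenient"])

    def t_strict(self, library_id: str) -> float:
        return float(self.per_library.loc[library_id, "t_strict"])

    def feasible_strict(self, library_id: str) -> bool:
        return bool(self.per_library.loc[library_id, "feasible_strict"])

    @property
    def library_ids(self) -> list[str]:
        return list(self.per_library.index)


class MockThresholdCalibrator(BaseEstimator):
    """Fit per-library thresholds on mock samples; transform environmental tables.

    Parameters
    ----------
    max_mismatch:
        Edit-distance allowance for "still assigned to an expected species".
    mode:
        Which threshold ``transform`` applies: ``"lenient"`` (keep iff
        proportion ≥ t) or ``"strict"`` (keep iff proportion > t).

    Attributes
    ----------
    thresholds_:
        Fitted :class:`ThresholdSet`.
    matches_:
        Per-library :class:`MockMatch` diagnostics.
    """

    def __init__(self, max_mismatch: int = DEFAULT_MAX_MISMATCH, mode: str = "lenient"):
        self.max_mismatch = max_mismatch
        self.mode = mode

    def fit(self,
            mocks: Mapping[str, tuple[CountMatrix, Sequence[SequenceRecord]]],
            expected: Sequence[SequenceRecord]) -> "MockThresholdCalibrator":
        """``mocks`` maps library_id → (one-sample mock CountMatrix, mock ASV sequences)."""
        rows, matches, diags = [], {}, {}
        for lib, (cm, seqs) in sorted(mocks.items()):
            m = match_mock(cm, seqs, expected, self.max_mismatch)
            t_len = lenient_threshold(m)
            t_str, feasible = strict_threshold(m)
            matched = m.matched[m.matched["reads"] > 0]
            diags[lib] = {
                "lenient_asv": matched["reads"].idxmin(),
                "n_matched": int(len(matched)),
                "n_asvs": int(len(m.table)),
                "total_reads": m.total_reads,
            }
            rows.append((lib, t_len, t_str, feasible))
            matches[lib] = m
            logger.info("library %s: t_lenient=%.4g t_strict=%.4g feasible=%s", lib, t_len, t_str, feasible)
        df = pd.DataFrame(rows, columns=["library_id", "t_lenient", "t_strict", "feasible_strict"])
        self.thresholds_ = ThresholdSet(df.set_index("library_id"), diags)
        self.matches_ = matches
        return self

    def transform(self, env: CountMatrix, meta: SampleMetadata) -> CountMatrix:
        if not hasattr(self, "thresholds_"):
            raise ValueError("MockThresholdCalibrator is not fitted")
        return apply_threshold(env, meta, self.thresholds_, mode=self.mode)


def apply_threshold(env: CountMatrix, meta: SampleMetadata, thresholds: ThresholdSet,
                    mode: str = "lenient") -> CountMatrix:
    """Filter each sample by its own library's threshold.

    Proportions are computed against the sample's total reads *before*
    filtering. Lenient mode keeps a cell iff proportion ≥ t_lenient(library);
    strict mode iff proportion > t_strict(library). ASVs left with zero reads
    everywhere are dropped.
    """
    if mode not in ("lenient", "strict"):
        raise ValueError(f"unknown mode {mode!r}")
    out = env.counts.copy()
    known = set(thresholds.library_ids)
    for sample in env.sample_ids:
        lib = meta.library_of(sample)
        if lib not in known:
            raise ValueError(f"sample {sample!r} maps to library {lib!r} with no calibrated threshold")
        total = out.loc[sample].sum()
        if total == 0:
            continue
        props = out.loc[sample] / total
        if mode == "lenient":
            keep = props >= thresholds.t_lenient(lib)
        else:
            keep = props > thresholds.t_strict(lib)
        removed = int((~keep & (out.loc[sample] > 0)).sum())
        out.loc[sample, ~keep] = 0
        logger.info("sample %s (%s, %s): %d ASVs removed", sample, lib, mode, removed)
    return CountMatrix(out).drop_empty_asvs()


@dataclass
class DatasetPartition:
    """The three derived datasets plus a per-cell removal log."""

    main: CountMatrix
    strict: CountMatrix
    low_abundant: CountMatrix
    removal_log: pd.DataFrame  # columns: sample, asv, reads, proportion, identity_pct, in_low_abundant


def partition_datasets(env: CountMatrix, meta: SampleMetadata, thresholds: ThresholdSet,
                       assign: AssignmentTable,
                       low_identity_min: float = DEFAULT_LOW_IDENTITY_MIN) -> DatasetPartition:
    """Partition an environmental table into main / strict / low-abundance datasets.

    ``env`` is expected to be already restricted to assigned, heterotrophic
    ASVs. The low-abundance dataset consists of exactly the cells the lenient
    filter removed, restricted to ASVs whose best-hit identity is strictly
    above ``low_identity_min`` (98% by default); per sample it is therefore
    disjoint from the main dataset by construction.
    """
    main = apply_threshold(env, meta, thresholds, mode="lenient")
    strict = apply_threshold(env, meta, thresholds, mode="strict")

    low = env.counts.copy()
    log_rows = []
    identity = {a: assign.identity_of(a) for a in env.asv_ids}
    for sample in env.sample_ids:
        total = env.counts.loc[sample].sum()
        if total == 0:
            low.loc[sample, :] = 0
            continue
        props = env.counts.loc[sample] / total
        lib = meta.library_of(sample)
        removed = (props < thresholds.t_lenient(lib)) & (env.counts.loc[sample] > 0)
        for asv in env.counts.columns[removed]:
            keep_low = identity[asv] > low_identity_min
            log_rows.append((sample, asv, int(env.counts.loc[sample, asv]),
                             float(props[asv]), identity[asv], keep_low))
        keep_cells = removed & pd.Series({a: identity[a] > low_identity_min for a in env.asv_ids})
        low.loc[sample, ~keep_cells] = 0
    low_cm = CountMatrix(low).drop_empty_asvs()
    log = pd.DataFrame(log_rows, columns=["sample", "asv", "reads", "proportion",
                                          "identity_pct", "in_low_abundant"])
    return DatasetPartition(main=main, strict=strict, low_abundant=low_cm, removal_log=log)
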