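"""Alpha diversity, rarefaction, group summaries and read accounting.

Shannon diversity uses the natural logarithm (the vegan default). Rarefaction
is analytic: the expected ASV richness in a random subsample of n reads from
a sample with N total reads and per-ASV counts N_i is

    E[S_n] = Σ_i [ 1 − C(N − N_i, n) / C(N, n) ],

the hypergeometric form vegan's ``rarefy`` implements; it is deterministic,
no resampling involved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .assign import AssignmentTable
from .io import CountMatrix, SampleMetadata


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def shannon(counts: Sequence[int] | np.ndarray, base: float | None = None) -> float:
    """Shannon index H = −Σ p_i log p_i over positive counts (natural log default)."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("negative counts")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    p = c / c.sum()
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


@dataclass
class RarefactionCurve:
    sample_id: str
    depths: np.ndarray
    expected_richness: np.ndarray


def _expected_richness(counts: np.ndarray, n: int) -> float:
    N = counts.sum()
    # log C(N - N_i, n) - log C(N, n), with C(N - N_i, n) = 0 when N - N_i < n
    with np.errstate(invalid="ignore"):
        log_c_full = gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)
        M = N - counts
        ok = M >= n
        log_c = gammaln(M[ok] + 1) - gammaln(n + 1) - gammaln(M[ok] - n + 1)
    miss = np.zeros(counts.size)
    miss[ok] = np.exp(log_c - log_c_full)
    return float((1.0 - miss).sum())


def rarefaction(counts: Sequence[int] | np.ndarray, depths: Sequence[int],
                sample_id: str = "") -> RarefactionCurve:
    """Analytic rarefaction curve for one sample's count vector."""
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector")
    N = int(c.sum())
    d = np.asarray(sorted(depths), dtype=np.int64)
    if (d < 1).any():
        raise ValueError("rarefaction depths must be ≥ 1")
    if (d > N).any():
        raise ValueError(f"rarefaction depth exceeds sample total {N}")
    values = np.array([_expected_richness(c, int(n)) for n in d])
    return RarefactionCurve(sample_id=sample_id, depths=d, expected_richness=values)


def rarefaction_table(cm: CountMatrix, n_points: int = 20) -> pd.DataFrame:
    """Rarefaction curves for every sample, at n_points evenly spaced depths."""
    rows = []
    for sid in cm.sample_ids:
        c = cm.counts.loc[sid].values
        total = int(c.sum())
        depths = np.unique(np.linspace(1, total, n_points, dtype=np.int64))
        curve = rarefaction(c, depths, sample_id=sid)
        rows.extend((sid, int(n), v) for n, v in zip(curve.depths, curve.expected_richness))
    return pd.DataFrame(rows, columns=["sample", "depth", "expected_richness"])


def group_summary(cm: CountMatrix, meta: SampleMetadata, key: str) -> pd.DataFrame:
    """Per-group mean ± sd of ASV richness and read totals.

    ``key`` is a metadata column (``depth_m`` or ``island``). Sample standard
    deviation (n−1); single-sample groups report sd 0 and are flagged.
    """
    if key not in meta.table.columns:
        raise ValueError(f"unknown grouping key {key!r}")
    env = meta.environmental()
    richness = (cm.counts > 0).sum(axis=1)
    totals = cm.counts.sum(axis=1)
    rows = []
    for group, members in env.groupby(key).groups.items():
        samples = [s for s in members if s in cm.counts.index]
        if not samples:
            warnings.warn(f"group {group!r} has no samples in the count table; omitted")
            continue
        r = richness[samples].astype(float)
        t = totals[samples].astype(float)
        single = len(samples) == 1
        rows.append((group, len(samples),
                     r.mean(), 0.0 if single else r.std(ddof=1),
                     t.mean(), 0.0 if single else t.std(ddof=1),
                     single))
    return pd.DataFrame(rows, columns=[key, "n_samples", "richness_mean", "richness_sd",
                                       "reads_mean", "reads_sd", "single_sample"]).set_index(key)


@dataclass
class TaxonProfile:
    """Division-level ASV proportions with divisions < min_prop lumped as Others."""

    group: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")


OTHERS = "Others"


def taxon_profile(asv_set: Sequence[str], assign: AssignmentTable,
                  min_prop: float = 0.02, group: str = "") -> TaxonProfile:
    """Proportion of ASVs per division; divisions below ``min_prop`` go to Others."""
    asvs = list(asv_set)
    if not asvs:
        raise ValueError("empty ASV set")
    divisions = pd.Series({a: assign.division_of(a) for a in asvs})
    if divisions.isna().any():
        raise ValueError(f"unassigned ASVs in profile: {list(divisions.index[divisions.isna()])[:5]}")
    props = divisions.value_counts(normalize=True)
    out: dict[str, float] = {}
    others = 0.0
    for div, p in props.items():
        if p < min_prop:
            others += p
        else:
            out[div] = float(p)
    if others > 0:
        out[OTHERS] = others
    return TaxonProfile(group=group, proportions=out)


def pipeline_report(raw_total: int, n_samples: int, assigned_total: int,
                    filtered_total: int, heterotroph_total: int) -> dict:
    """Read-accounting summary across pipeline stages.

    Returns raw and presentation-rounded values: mean reads per sample (raw,
    and in millions to one decimal), percentage of quality-filtered reads that
    were assigned (>80% identity), and percentage of assigned reads retained
    as heterotrophic protists. Rounding is half-up.
    """
    for name, v in [("raw_total", raw_total), ("assigned_total", assigned_total),
                    ("filtered_total", filtered_total), ("heterotroph_total", heterotroph_total)]:
        if v < 0:
            raise ValueError(f"{name} is negative")
    if n_samples <= 0 or filtered_total == 0 or assigned_total == 0:
        raise ValueError("zero denominator in pipeline report")
    if assigned_total > filtered_total or heterotroph_total > assigned_total:
        raise ValueError("stage totals must be nested")
    mean_reads = raw_total / n_samples
    assigned_pct = 100.0 * assigned_total / filtered_total
    het_pct = 100.0 * heterotroph_total / assigned_total
    return {
        "mean_reads_per_sample": mean_reads,
        "mean_reads_per_sample_millions": _round_half_up(mean_reads / 1e6, 1),
        "assigned_pct_raw": assigned_pct,
        "assigned_pct": int(_round_half_up(assigned_pct)),
        "heterotroph_pct_raw": het_pct,
        "heterotroph_pct": int(_round_half_up(het_pct)),
    }
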