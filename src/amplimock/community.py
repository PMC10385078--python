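"""Presence/absence beta diversity: Jaccard distances, NMDS, PermANOVA.

PermANOVA partitions the squared inter-sample distances: with n samples and
g groups of sizes n_g,

    SS_total  = Σ_{i<j} d_ij² / n
    SS_within = Σ_g Σ_{i<j ∈ g} d_ij² / n_g
    pseudo-F  = (SS_between / (g−1)) / (SS_within / (n−g)),

and the p-value is permutational: p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)
under free permutation of sample labels, so p ≥ 1/(n_perm+1). The two-factor
nested variant decomposes sequentially (island first, then depth within
island) with each term tested against the residual.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample distance matrix with zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (d < 0).any():
            raise ValueError("negative distances")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


def jaccard_matrix(presence: pd.DataFrame | CountMatrix) -> DistanceMatrix:
    """Jaccard distances d(i,j) = 1 − |A_i ∩ A_j| / |A_i ∪ A_j| on presence/absence."""
    if isinstance(presence, CountMatrix):
        presence = presence.presence()
    x = presence.values.astype(bool)
    empty = ~x.any(axis=1)
    if empty.any():
        raise ValueError(f"samples with no ASVs: {list(presence.index[empty])}")
    d = squareform(pdist(x, metric="jaccard"))
    return DistanceMatrix(list(presence.index), d)


# ---------------------------------------------------------------------------
# NMDS

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples × k
    stress: float              # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool


class NMDS(BaseEstimator):
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    SMACOF iterative majorization with isotonic regression over ``n_starts``
    random initializations (delegated to scikit-learn); the reported solution
    is the best start. Deterministic under a fixed ``random_state``.
    """

    def __init__(self, n_components: int = 2, n_starts: int = 20, max_iter: int = 300,
                 tol: float = 1e-7, random_state: int = 0):
        self.n_components = n_components
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, d: DistanceMatrix) -> "NMDS":
        from sklearn.manifold import MDS

        if d.n <= self.n_components:
            raise ValueError("need more samples than ordination dimensions")
        if not d.data.any():
            raise ValueError("all distances are zero")
        mds = MDS(n_components=self.n_components, metric_mds=False, n_init=self.n_starts,
                  max_iter=self.max_iter, eps=self.tol, metric="precomputed", init="random",
                  random_state=self.random_state, normalized_stress=True)
        coords = mds.fit_transform(d.data)
        self.embedding_ = pd.DataFrame(coords, index=d.ids,
                                       columns=[f"NMDS{k + 1}" for k in range(self.n_components)])
        self.stress_ = float(mds.stress_)
        self.n_iter_ = int(mds.n_iter_)
        self.converged_ = self.n_iter_ < self.max_iter
        return self

    def fit_transform(self, d: DistanceMatrix) -> pd.DataFrame:
        return self.fit(d).embedding_


def nmds(d: DistanceMatrix, k: int = 2, n_starts: int = 20, max_iter: int = 300,
         tol: float = 1e-7, seed: int = 0) -> OrdinationResult:
    est = NMDS(n_components=k, n_starts=n_starts, max_iter=max_iter, tol=tol,
               random_state=seed).fit(d)
    return OrdinationResult(coordinates=est.embedding_, stress=est.stress_,
                            n_starts=n_starts, converged=est.converged_)


# ---------------------------------------------------------------------------
# PermANOVA

@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_perm: int
    seed: int | None = None
    terms: pd.DataFrame | None = field(default=None, repr=False)


def _encode(labels: Sequence) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    return codes, len(uniques)


def _ss_within(dsq: np.ndarray, codes: np.ndarray, g: int) -> float:
    """Σ_g (within-group pairwise d²)/n_g via one-hot quadratic forms."""
    x = np.zeros((dsq.shape[0], g))
    x[np.arange(dsq.shape[0]), codes] = 1.0
    sizes = x.sum(axis=0)
    within_pair_sums = np.einsum("ig,ij,jg->g", x, dsq, x) / 2.0
    return float((within_pair_sums / sizes).sum())


def _f_stat(dsq: np.ndarray, codes: np.ndarray, g: int, ss_total: float) -> tuple[float, float]:
    n = dsq.shape[0]
    ss_w = _ss_within(dsq, codes, g)
    ss_b = ss_total - ss_w
    f = (ss_b / (g - 1)) / (ss_w / (n - g))
    return f, ss_b / ss_total


def permanova(d: DistanceMatrix, labels: Sequence, n_perm: int = 999,
              seed: int | None = 0, exhaustive: bool = False) -> PermanovaResult:
    """One-factor PermANOVA with a free-permutation p-value.

    With ``exhaustive=True`` all n! label permutations are enumerated and
    p = #{F_perm ≥ F_obs} / n! (the identity permutation included); only
    sensible for small n.
    """
    codes, g = _encode(labels)
    n = d.n
    if len(codes) != n:
        raise ValueError("one label per sample required")
    if g < 2:
        raise ValueError("need at least two groups")
    if n - g < 1:
        raise ValueError("no residual degrees of freedom")
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be ≥ 1")
    dsq = d.data ** 2
    ss_total = dsq[np.triu_indices(n, k=1)].sum() / n
    f_obs, r2 = _f_stat(dsq, codes, g, ss_total)

    if exhaustive:
        if n > 9:
            raise ValueError("exhaustive enumeration limited to n ≤ 9")
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            f_p, _ = _f_stat(dsq, codes[list(perm)], g, ss_total)
            hits += f_p >= f_obs - 1e-12
            total += 1
        return PermanovaResult(pseudo_F=f_obs, R2=r2, p_value=hits / total,
                               n_perm=total, seed=None)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_p, _ = _f_stat(dsq, rng.permutation(codes), g, ss_total)
        hits += f_p >= f_obs - 1e-12
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(pseudo_F=f_obs, R2=r2, p_value=p, n_perm=n_perm, seed=seed)


def pairwise_permanova(d: DistanceMatrix, labels: Sequence, n_perm: int = 999,
                       seed: int | None = 0) -> pd.DataFrame:
    """PermANOVA on every pair of groups, with Benjamini–Hochberg adjustment.

    Returns one row per pair: group_a, group_b, pseudo_F, R2, p_value, p_adjusted.
    """
    labels = pd.Series(list(labels), index=d.ids)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rows = []
    for a, b in itertools.combinations(groups, 2):
        ids = list(labels.index[labels.isin([a, b])])
        if len(ids) < 3:
            warnings.warn(f"pair ({a}, {b}) has fewer than 3 samples; skipped")
            continue
        res = permanova(d.subset(ids), labels[ids].values, n_perm=n_perm, seed=seed)
        rows.append((a, b, res.pseudo_F, res.R2, res.p_value))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "pseudo_F", "R2", "p_value"])
    if not out.empty:
        out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def nested_permanova(d: DistanceMatrix, island: Sequence, depth: Sequence,
                     n_perm: int = 999, seed: int | None = 0) -> PermanovaResult:
    """Two-factor nested PermANOVA: islands, then depths nested within islands.

    Sequential (Type-I) decomposition: the island term is the between-island
    sum of squares; the nested term is the additional SS explained by the
    island × depth cells (depth levels treated as distinct per island); both
    are tested against the residual under free permutation of samples. The
    returned result carries the island term's statistics, with a ``terms``
    table holding both terms and the residual (their R² sums to 1).
    """
    isl = np.asarray(island)
    dep = np.asarray(depth)
    n = d.n
    if len(isl) != n or len(dep) != n:
        raise ValueError("one island and one depth label per sample required")
    cells = np.array([f"{a}|{b}" for a, b in zip(isl, dep)])
    isl_codes, a = _encode(isl)
    cell_codes, c = _encode(cells)
    if c >= n:
        raise ValueError("no residual degrees of freedom: every island×depth cell has one sample")
    if c <= a:
        raise ValueError("depth adds no levels within islands")

    dsq = d.data ** 2
    ss_total = dsq[np.triu_indices(n, k=1)].sum() / n
    df_island, df_depth, df_resid = a - 1, c - a, n - c

    def decompose(i_codes: np.ndarray, c_codes: np.ndarray) -> tuple[float, float]:
        ss_island = ss_total - _ss_within(dsq, i_codes, a)
        ss_cells = ss_total - _ss_within(dsq, c_codes, c)
        ss_resid = ss_total - ss_cells
        ms_resid = ss_resid / df_resid
        f_i = (ss_island / df_island) / ms_resid
        f_d = ((ss_cells - ss_island) / df_depth) / ms_resid
        return f_i, f_d

    ss_island = ss_total - _ss_within(dsq, isl_codes, a)
    ss_cells = ss_total - _ss_within(dsq, cell_codes, c)
    if ss_total - ss_cells <= 0:
        raise ValueError("zero residual variation: samples within island×depth cells are identical")
    f_i_obs, f_d_obs = decompose(isl_codes, cell_codes)

    rng = np.random.default_rng(seed)
    hits_i = hits_d = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_i, f_d = decompose(isl_codes[perm], cell_codes[perm])
        hits_i += f_i >= f_i_obs - 1e-12
        hits_d += f_d >= f_d_obs - 1e-12
    p_i = (1 + hits_i) / (1 + n_perm)
    p_d = (1 + hits_d) / (1 + n_perm)

    terms = pd.DataFrame(
        {
            "df": [df_island, df_depth, df_resid],
            "SS": [ss_island, ss_cells - ss_island, ss_total - ss_cells],
            "R2": [ss_island / ss_total, (ss_cells - ss_island) / ss_total,
                   (ss_total - ss_cells) / ss_total],
            "pseudo_F": [f_i_obs, f_d_obs, np.nan],
            "p_value": [p_i, p_d, np.nan],
        },
        index=["island", "depth_within_island", "residual"],
    )
    return PermanovaResult(pseudo_F=f_i_obs, R2=ss_island / ss_total, p_value=p_i,
                           n_perm=n_perm, seed=seed, terms=terms)
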