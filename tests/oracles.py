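"""Independent brute-force oracles used only by the tests."""

from __future__ import annotations

import itertools

import numpy as np


def nw_edit_distance(a: str, b: str) -> int:
    """Textbook Needleman–Wunsch / Levenshtein DP (unit costs)."""
    n, m = len(a), len(b)
    prev = list(range(m + 1))
    for i in range(1, n + 1):
        cur = [i] + [0] * m
        for j in range(1, m + 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1,
                         prev[j - 1] + (a[i - 1] != b[j - 1]))
        prev = cur
    return prev[m]


def permanova_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F by direct double loops over pairs (no linear algebra tricks)."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    ss_between = ss_total - ss_within
    g = len(groups)
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova_exhaustive_p(d: np.ndarray, labels: np.ndarray) -> float:
    """Exact permutation p by full enumeration of label orderings."""
    f_obs = permanova_f(d, labels)
    labels = np.asarray(labels)
    hits = total = 0
    for perm in itertools.permutations(range(len(labels))):
        hits += permanova_f(d, labels[list(perm)]) >= f_obs - 1e-12
        total += 1
    return hits / total


def rarefy_monte_carlo(counts: np.ndarray, depth: int, n_draws: int, seed: int) -> tuple[float, float]:
    """Mean and standard error of subsampled richness over random draws."""
    rng = np.random.default_rng(seed)
    reads = np.repeat(np.arange(len(counts)), counts)
    richness = np.empty(n_draws)
    for k in range(n_draws):
        sub = rng.choice(reads, size=depth, replace=False)
        richness[k] = len(np.unique(sub))
    return float(richness.mean()), float(richness.std(ddof=1) / np.sqrt(n_draws))
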