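"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written from the definition of each quantity, by
exhaustive enumeration, and stays independent of the code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_lca(taxa: set[str], nodes: dict[str, tuple[str | None]]) -> str:
    """LCA by ancestor-set intersection; deepest = longest path to root.

    ``nodes`` maps taxon id -> parent id (None for root).
    """

    def path(t: str) -> list[str]:
        out = [t]
        while nodes[out[-1]] is not None:
            out.append(nodes[out[-1]])
        return out

    common = set(path(next(iter(taxa))))
    for t in taxa:
        common &= set(path(t))
    return max(common, key=lambda t: len(path(t)))


def brute_candidates(ranges: dict[str, tuple[float, float]]) -> set[str]:
    """Direct evaluation of the overlap-with-best candidate rule."""
    if not ranges:
        return set()
    best = max(hi for (_, hi) in ranges.values())
    best_taxa = [t for t, (_, hi) in ranges.items() if hi == best]
    m = min(ranges[t][0] for t in best_taxa)
    return {t for t, (_, hi) in ranges.items() if hi >= m}


def brute_rarefaction(counts: list[int], n: int) -> float:
    """Mean richness over every size-n subset of individual reads."""
    reads = [i for i, c in enumerate(counts) for _ in range(c)]
    richness = [
        len(set(reads[i] for i in combo))
        for combo in itertools.combinations(range(len(reads)), n)
    ]
    return sum(richness) / len(richness)


def brute_accumulation(presence: np.ndarray, t: int) -> float:
    """Mean richness over every size-t subset of sites."""
    sites = range(presence.shape[0])
    vals = [
        int(presence[list(combo)].any(axis=0).sum())
        for combo in itertools.combinations(sites, t)
    ]
    return sum(vals) / len(vals)


def brute_raup_crick(a: int, b: int, j: int, pool: int) -> float:
    """P(shared >= j) by enumerating all C(pool, b) draws of the second
    sample against a fixed first sample of a taxa."""
    first = set(range(a))
    hits = total = 0
    for combo in itertools.combinations(range(pool), b):
        total += 1
        if len(first & set(combo)) >= j:
            hits += 1
    return hits / total


def permanova_f_r2(d: np.ndarray, labels: list) -> tuple[float, float]:
    """Pseudo-F and R2 straight from the sum-of-squares definitions."""
    labels = list(labels)
    n = len(labels)
    groups = sorted(set(labels), key=str)
    a = len(groups)
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_within += sum(
            d[i, j] ** 2 for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, ss_between / ss_total


def brute_permanova_exhaustive(d: np.ndarray, labels: list) -> tuple[float, float, float]:
    """(F, R2, exact p) over ALL distinct label orderings (small n only)."""
    f_obs, r2 = permanova_f_r2(d, labels)
    perms = set(itertools.permutations(labels))
    exceed = sum(permanova_f_r2(d, list(p))[0] >= f_obs - 1e-12 for p in perms)
    return f_obs, r2, exceed / len(perms)


def brute_upgma_cophenetic(d: np.ndarray) -> np.ndarray:
    """Cophenetic (merge-height) matrix from a naive average-linkage run.

    Cluster distance = arithmetic mean of all member-pair distances in the
    ORIGINAL matrix; cophenetic entry for two leaves = the distance at
    which their clusters merged.
    """
    n = d.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    coph = np.zeros((n, n))

    def cdist(A: list[int], B: list[int]) -> float:
        return float(np.mean([d[i, j] for i in A for j in B]))

    while len(clusters) > 1:
        best = None
        for x, y in itertools.combinations(range(len(clusters)), 2):
            dd = cdist(clusters[x], clusters[y])
            if best is None or dd < best[0]:
                best = (dd, x, y)
        dd, x, y = best
        for i in clusters[x]:
            for j in clusters[y]:
                coph[i, j] = coph[j, i] = dd
        merged = clusters[x] + clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    return coph
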