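"""Community-ecology statistics on presence-absence taxon tables.

Covers the inferential stages of the pipeline: analytic rarefaction
(per-replicate sequencing-depth checks), exact species accumulation over
sites, Raup-Crick dissimilarity under its hypergeometric null, one-way
PERMANOVA on a distance matrix, a permutation test for homogeneity of
multivariate dispersions, rank-based inverse-normal and cube-root distance
transforms, UPGMA clustering with Newick export, one-way richness ANOVA,
and aggregation of taxa into trophic (functional) groups.

All hypergeometric tail ratios are evaluated in log space (log-gamma), so
read depths of 1e5-1e6 do not overflow.  Every randomized operation takes
an explicit integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.special import gammaln

from .io_core import (
    CommunityMatrix,
    DistanceMatrix,
    ValidationError,
    validate_trophic_map,
)
from .repfilter import FinalTaxonTable

logger = logging.getLogger("dungdna")

DEFAULT_SEED = 0


def _log_choose(n, k):
    """log C(n, k); -inf where k > n or k < 0."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


# ---------------------------------------------------------------------------
# Rarefaction and accumulation
# ---------------------------------------------------------------------------


def rarefaction_curve(
    read_counts: np.ndarray | pd.Series, efforts: list[int] | np.ndarray
) -> pd.DataFrame:
    """Expected taxon richness in random subsamples of n reads.

    E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)], with N the total read
    count and N_i the reads of taxon i: each taxon contributes its
    probability of being included in a uniform draw of n reads without
    replacement.
    """
    counts = np.asarray(read_counts, dtype=np.int64)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValidationError("rarefaction needs at least one positive count")
    total = int(counts.sum())
    efforts = np.asarray(efforts, dtype=np.int64)
    if (efforts < 1).any() or (efforts > total).any():
        raise ValidationError(f"efforts must lie in [1, {total}]")
    rows = []
    log_total = _log_choose(total, efforts[:, None])  # (n_eff, 1)
    log_miss = _log_choose(total - counts[None, :], efforts[:, None])  # (n_eff, S)
    p_incl = 1.0 - np.exp(log_miss - log_total)
    expected = p_incl.sum(axis=1)
    for n, s in zip(efforts, expected):
        rows.append({"effort": int(n), "expected_richness": float(s)})
    return pd.DataFrame(rows)


def rarefaction_per_replicate(
    counts_df: pd.DataFrame, n_points: int = 20
) -> dict[str, pd.DataFrame]:
    """Rarefaction curve per replicate column of a taxon x column table."""
    out = {}
    for col in counts_df.columns:
        vec = counts_df[col].to_numpy()
        total = int(vec.sum())
        if total == 0:
            continue
        efforts = np.unique(np.linspace(1, total, num=min(n_points, total), dtype=np.int64))
        name = col if isinstance(col, str) else "_".join(map(str, col))
        out[name] = rarefaction_curve(vec, efforts)
    return out


def accumulation_exact(
    matrix: CommunityMatrix,
    sd_permutations: int = 1000,
    seed: int = DEFAULT_SEED,
) -> pd.DataFrame:
    """Exact species accumulation: the mean richness over all equally
    likely subsets of t sites, for t = 1..T.

    S(t) = sum_i [1 - C(T - T_i, t) / C(T, t)], T_i = number of sites
    holding taxon i.  The SD column is estimated by resampling random site
    orderings (cumulative-union richness at each t) under the given seed.
    """
    pres = matrix.presence().to_numpy()
    T = pres.shape[0]
    if T < 1:
        raise ValidationError("accumulation needs at least one site")
    occ = pres.sum(axis=0)  # T_i per taxon
    t_grid = np.arange(1, T + 1)
    log_total = _log_choose(T, t_grid[:, None])
    log_miss = _log_choose(T - occ[None, :], t_grid[:, None])
    expected = (1.0 - np.exp(log_miss - log_total)).sum(axis=1)

    sd = np.zeros(T)
    if sd_permutations > 0 and T > 1:
        rng = np.random.default_rng(seed)
        rich = np.empty((sd_permutations, T))
        for b in range(sd_permutations):
            order = rng.permutation(T)
            seen = np.cumsum(pres[order], axis=0) > 0
            rich[b] = seen.sum(axis=1)
        sd = rich.std(axis=0, ddof=1)
    return pd.DataFrame(
        {"effort": t_grid, "expected_richness": expected, "sd": sd}
    )


# ---------------------------------------------------------------------------
# Raup-Crick dissimilarity
# ---------------------------------------------------------------------------


def raup_crick_pair(a: int, b: int, j: int, pool: int) -> float:
    """P(X >= j) for X hypergeometric: draw b taxa from a pool of ``pool``
    of which a are in the first sample.  Small values mean the two samples
    share more taxa than expected by chance; disjoint samples give 1."""
    if j == 0:
        return 1.0
    # sf(j - 1) = P(X >= j)
    return float(stats.hypergeom.sf(j - 1, pool, a, b))


def raup_crick(matrix: CommunityMatrix) -> DistanceMatrix:
    """Raup-Crick dissimilarity between all sample pairs.

    The species pool is the set of taxa present in at least one sample of
    the analyzed matrix.  Empty samples and samples spanning the whole pool
    make the null degenerate; they are accepted with a warning and yield
    dissimilarity 1 from the tail formula.
    """
    pres = matrix.presence().to_numpy(dtype=bool)
    pool = int(pres.any(axis=0).sum())
    sizes = pres.sum(axis=1)
    n = pres.shape[0]
    if (sizes == 0).any():
        logger.warning("raup_crick: %d empty sample(s); their dissimilarities are 1",
                       int((sizes == 0).sum()))
    if (sizes == pool).any() and n > 1:
        logger.warning("raup_crick: sample(s) span the whole pool; null is degenerate")
    d = np.zeros((n, n))
    for i in range(n):
        for k in range(i + 1, n):
            j = int((pres[i] & pres[k]).sum())
            d[i, k] = d[k, i] = raup_crick_pair(int(sizes[i]), int(sizes[k]), j, pool)
    return DistanceMatrix(d, matrix.samples, transform="none")


# ---------------------------------------------------------------------------
# Distance transforms
# ---------------------------------------------------------------------------


def inverse_normal_transform(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal scores: Phi^{-1}((rank - 0.5) / n) with
    average ranks for ties.  A constant vector maps to all zeros (warned)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValidationError("inverse-normal transform needs >= 2 values")
    if np.all(v == v.flat[0]):
        logger.warning("inverse_normal_transform: constant input; output is constant")
        return np.zeros_like(v)
    ranks = stats.rankdata(v.ravel(), method="average")
    return stats.norm.ppf((ranks - 0.5) / v.size).reshape(v.shape)


def inverse_normal_distances(dist: DistanceMatrix) -> DistanceMatrix:
    """Inverse-normal transform of the off-diagonal entries, shifted to be
    non-negative so the result remains a dissimilarity matrix."""
    cond = dist.condensed()
    scores = inverse_normal_transform(cond)
    offset = float(-scores.min()) if scores.min() < 0 else 0.0
    scores = scores + offset
    n = dist.n
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = scores
    out = out + out.T
    dm = dist.with_values(out, transform="inverse-normal")
    logger.info("inverse_normal_distances: offset %.4f applied", offset)
    return dm


def cube_transform(dist: DistanceMatrix, exponent: float = 1.0 / 3.0) -> DistanceMatrix:
    """Elementwise cube-root (n^(1/3)) rescaling of the distances."""
    return dist.with_values(np.power(dist.values, exponent), transform="cube-root")


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    F: float
    R2: float
    p: float
    n_permutations: int

    def report(self) -> str:
        return (
            f"PERMANOVA: pseudo-F = {self.F:.4f}, R2 = {self.R2:.4f}, "
            f"p = {self.p:.4f} ({self.n_permutations} permutations)"
        )


def _permanova_ss(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and integer group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(len(idx), k=1)].sum() / len(idx)
    return ss_total, ss_within


def permanova(
    dist: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_permutations: int = 999,
    seed: int = DEFAULT_SEED,
) -> PermanovaResult:
    """One-way PERMANOVA: partition squared dissimilarities among groups
    and test the pseudo-F statistic by random label permutation.

    p uses the add-one estimator (1 + #{F_perm >= F_obs}) / (1 + m).
    """
    labels = np.asarray(groups)
    if len(labels) != dist.n:
        raise ValidationError("group labels must match distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    n = dist.n
    d2 = dist.values**2

    def f_stat(c: np.ndarray) -> tuple[float, float]:
        ss_total, ss_within = _permanova_ss(d2, c, a)
        ss_between = ss_total - ss_within
        f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
        r2 = ss_between / ss_total if ss_total > 0 else 0.0
        return f, r2

    f_obs, r2 = f_stat(codes)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        f_perm, _ = f_stat(rng.permutation(codes))
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    result = PermanovaResult(F=float(f_obs), R2=float(r2), p=float(p),
                             n_permutations=n_permutations)
    logger.info("permanova: %s", result.report())
    return result


# ---------------------------------------------------------------------------
# Homogeneity of multivariate dispersions
# ---------------------------------------------------------------------------


def _pcoa_axes(dist: DistanceMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates axes split into real (positive-eigenvalue) and
    imaginary (negative-eigenvalue) parts, each scaled by sqrt(|lambda|)."""
    d2 = dist.values**2
    n = dist.n
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    lam, vec = np.linalg.eigh((g + g.T) / 2)
    tol = 1e-10 * max(1.0, np.abs(lam).max())
    pos = lam > tol
    neg = lam < -tol
    real_axes = vec[:, pos] * np.sqrt(lam[pos])
    imag_axes = vec[:, neg] * np.sqrt(-lam[neg])
    return real_axes, imag_axes


def _centroid_distances(
    real_axes: np.ndarray, imag_axes: np.ndarray, codes: np.ndarray
) -> np.ndarray:
    """Distance of each sample to its group centroid in the PCoA embedding,
    with the negative-eigenvalue axes contributing negatively:
    z = sqrt(max(0, |x_real - c_real|^2 - |x_imag - c_imag|^2))."""
    z = np.empty(len(codes))
    for g in np.unique(codes):
        idx = np.flatnonzero(codes == g)
        c_r = real_axes[idx].mean(axis=0)
        sq = ((real_axes[idx] - c_r) ** 2).sum(axis=1)
        if imag_axes.shape[1]:
            c_i = imag_axes[idx].mean(axis=0)
            sq = sq - ((imag_axes[idx] - c_i) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(0.0, sq))
    return z


def dispersion_test(
    dist: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_permutations: int = 999,
    seed: int = DEFAULT_SEED,
) -> tuple[float, float]:
    """Permutation test for homogeneity of multivariate group dispersions.

    Embeds the distances by PCoA, computes each sample's distance to its
    group centroid (negative-eigenvalue axes subtract), and tests the
    one-way F on those distances by permuting group labels.
    Returns (F, p).
    """
    labels = np.asarray(groups)
    if len(labels) != dist.n:
        raise ValidationError("group labels must match distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("dispersion test needs >= 2 groups")
    if np.allclose(dist.values, 0):
        raise ValidationError("all samples coincident; dispersion undefined")
    real_axes, imag_axes = _pcoa_axes(dist)

    def f_of(c: np.ndarray) -> float:
        z = _centroid_distances(real_axes, imag_axes, c)
        groups_z = [z[c == g] for g in np.unique(c)]
        ms_between, ms_within = _anova_ms(groups_z)
        return np.inf if ms_within == 0 else ms_between / ms_within

    f_obs = f_of(codes)
    rng = np.random.default_rng(seed)
    exceed = sum(f_of(rng.permutation(codes)) >= f_obs for _ in range(n_permutations))
    p = (1 + exceed) / (1 + n_permutations)
    logger.info("dispersion_test: F = %.4f, p = %.4f", f_obs, p)
    return float(f_obs), float(p)


def _anova_ms(groups_z: list[np.ndarray]) -> tuple[float, float]:
    allz = np.concatenate(groups_z)
    grand = allz.mean()
    a = len(groups_z)
    n = len(allz)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups_z)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups_z)
    return ss_between / (a - 1), ss_within / (n - a) if n > a else np.nan


# ---------------------------------------------------------------------------
# Richness ANOVA
# ---------------------------------------------------------------------------


def richness_anova(richness: np.ndarray | list[float], groups: list[str] | np.ndarray) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of per-sample richness across habitats;
    returns (F, p) from the F distribution."""
    richness = np.asarray(richness, dtype=float)
    labels = np.asarray(groups)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    samples = [richness[labels == g] for g in uniq]
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(richness) == 0:
        raise ValidationError("zero variance within and between groups")
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# UPGMA clustering
# ---------------------------------------------------------------------------


@dataclass
class Dendrogram:
    """Average-linkage merge tree; heights are merge distance / 2, so leaf
    -to-ancestor path lengths are ultrametric."""

    merges: np.ndarray  # scipy linkage matrix
    labels: list[str]

    def merge_heights(self) -> np.ndarray:
        return self.merges[:, 2] / 2.0

    def to_newick(self) -> str:
        root = to_tree(self.merges)

        def height(node) -> float:
            return 0.0 if node.is_leaf() else node.dist / 2.0

        def render(node, parent_height: float) -> str:
            length = parent_height - height(node)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            left = render(node.left, height(node))
            right = render(node.right, height(node))
            return f"({left},{right}):{length:.10g}"

        if root.is_leaf():
            return f"{self.labels[root.id]}:0;"
        left = render(root.left, height(root))
        right = render(root.right, height(root))
        return f"({left},{right});"


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering of the samples."""
    if dist.n < 2:
        raise ValidationError("UPGMA needs >= 2 leaves")
    z = linkage(dist.condensed(), method="average")
    return Dendrogram(merges=z, labels=list(dist.labels))


# ---------------------------------------------------------------------------
# Trophic aggregation
# ---------------------------------------------------------------------------


def trophic_aggregate(
    table: CommunityMatrix | FinalTaxonTable, mapping: dict[str, str]
) -> CommunityMatrix:
    """Presence matrix over trophic groups: a group is present in a sample
    iff any member taxon is.  Taxa absent from the map fall back to
    'nonspecific' with a warning.

    Accepts a sample x taxon community matrix, or a final taxon table (in
    which case rows are habitats and presence comes from the habitat flags).
    """
    mapping = validate_trophic_map(mapping)
    if isinstance(table, FinalTaxonTable):
        pres = table.table[table.habitats].T.astype(bool)  # habitat x taxon
        habitats = None
    else:
        pres = table.presence().astype(bool)
        habitats = table.habitats or None
    unmapped = [t for t in pres.columns if t not in mapping]
    if unmapped:
        logger.warning("trophic_aggregate: %d unmapped taxa -> 'nonspecific'", len(unmapped))
    group_of = {t: mapping.get(t, "nonspecific") for t in pres.columns}
    groups = sorted(set(group_of.values()))
    out = pd.DataFrame(False, index=pres.index, columns=groups)
    for taxon, grp in group_of.items():
        out[grp] |= pres[taxon]
    return CommunityMatrix(out.astype(int), habitats)
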