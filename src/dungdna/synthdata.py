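"""Known-truth synthetic inputs with the statistical structure the
analysis assumes.

The generator emulates a small multi-habitat dung eDNA survey: a balanced
rank taxonomy; habitat-specific taxon pools with a configurable shared
fraction; strongly right-skewed (log-normal) taxon abundances with one
dominant taxon holding a fixed share of reads; two PCR replicates per
sample with per-taxon Bernoulli detection dropout; multinomial read
allocation at fixed per-replicate depth; host reads mixed in; and hit
tables drawn directly from per-rank identity ranges (identity draws rather
than sequence evolution — the assignment rules consume identities, nothing
else).

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_core import (
    Hit,
    HitTable,
    ReplicateCountTable,
    TaxonNode,
    TaxonomyTable,
    ValidationError,
)

logger = logging.getLogger("dungdna")

HOST_TAXON_ID = "host_sp"

_HABITAT_NAMES = ("grassland", "meadow", "forest")


@dataclass(frozen=True)
class IdentityModel:
    """Percent-identity ranges for reference hits, by relatedness to the
    query's true species.  Defaults keep ranks separable: relatives never
    reach the species threshold."""

    intra: tuple[float, float] = (98.5, 100.0)
    congener: tuple[float, float] = (88.0, 95.0)
    confamilial: tuple[float, float] = (83.0, 89.0)
    other: tuple[float, float] = (75.0, 82.0)

    def __post_init__(self):
        for lo, hi in (self.intra, self.congener, self.confamilial, self.other):
            if not (0 <= lo <= hi <= 100):
                raise ValidationError("identity ranges must satisfy 0 <= lo <= hi <= 100")


@dataclass(frozen=True)
class TaxonomyShape:
    n_orders: int = 6
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 4

    def n_species(self) -> int:
        return (
            self.n_orders
            * self.families_per_order
            * self.genera_per_family
            * self.species_per_genus
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters for the synthetic survey.

    Defaults mirror the emulated study: 3 habitats x 3 samples with one
    failed sample (8 analyzed), 2 PCR replicates each, ~60 taxa in play,
    a dominant taxon at 37% of community reads, and per-replicate taxon
    detection dropout.
    """

    n_habitats: int = 3
    samples_per_habitat: int = 3
    replicates_per_sample: int = 2
    dropped_samples: tuple[str, ...] = ("tx6",)  # failed PCR; 8 analyzed samples
    shape: TaxonomyShape = field(default_factory=TaxonomyShape)
    pool_size: int = 25  # taxa per habitat pool
    overlap_fraction: float = 0.3  # fraction of each pool shared by all habitats
    abundance_sigma: float = 1.5  # log-normal shape
    dominant_fraction: float = 0.37  # read share of the most abundant taxon
    detection_prob: float = 0.85  # per-taxon, per-replicate
    host_read_fraction: float = 0.2
    reads_per_replicate: int = 40_000
    identity: IdentityModel = field(default_factory=IdentityModel)
    seed: int = 0

    def __post_init__(self):
        for p in (self.overlap_fraction, self.detection_prob, self.host_read_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities/fractions must lie in [0, 1]")
        if not (0.0 < self.dominant_fraction < 1.0):
            raise ValidationError("dominant_fraction must lie in (0, 1)")
        if min(self.n_habitats, self.samples_per_habitat, self.replicates_per_sample,
               self.pool_size, self.reads_per_replicate) < 1:
            raise ValidationError("design counts must be positive")


def habitat_names(n: int) -> list[str]:
    return [(_HABITAT_NAMES[i] if i < len(_HABITAT_NAMES) else f"habitat{i + 1}") for i in range(n)]


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


def make_taxonomy(shape: TaxonomyShape | None = None, seed: int = 0,
                  include_host: bool = True) -> TaxonomyTable:
    """Balanced rank tree (order/family/genus/species under one kingdom)
    with systematic ids like ``o2.f1.g2.s3``.  Optionally adds a host
    lineage whose species id is :data:`HOST_TAXON_ID`.

    The tree is fully determined by its shape; ``seed`` is accepted for
    interface uniformity.
    """
    shape = shape or TaxonomyShape()
    if shape.n_species() == 0:
        raise ValidationError("taxonomy shape yields zero species")
    nodes: dict[str, TaxonNode] = {
        "root": TaxonNode("root", "root", None),
        "k1": TaxonNode("Animalia", "kingdom", "root"),
    }
    for o in range(1, shape.n_orders + 1):
        oid = f"o{o}"
        nodes[oid] = TaxonNode(f"Order{o}", "order", "k1")
        for f in range(1, shape.families_per_order + 1):
            fid = f"{oid}.f{f}"
            nodes[fid] = TaxonNode(f"Family{o}.{f}", "family", oid)
            for g in range(1, shape.genera_per_family + 1):
                gid = f"{fid}.g{g}"
                nodes[gid] = TaxonNode(f"Genus{o}.{f}.{g}", "genus", fid)
                for s in range(1, shape.species_per_genus + 1):
                    sid = f"{gid}.s{s}"
                    nodes[sid] = TaxonNode(f"Species{o}.{f}.{g}.{s}", "species", gid)
    if include_host:
        nodes["host_o"] = TaxonNode("Artiodactyla", "order", "k1")
        nodes["host_f"] = TaxonNode("Bovidae", "family", "host_o")
        nodes["host_g"] = TaxonNode("Bos", "genus", "host_f")
        nodes[HOST_TAXON_ID] = TaxonNode("Bos taurus", "species", "host_g")
    return TaxonomyTable(nodes)


# ---------------------------------------------------------------------------
# Hit simulation
# ---------------------------------------------------------------------------


def _relatedness(taxonomy: TaxonomyTable, a: str, b: str) -> str:
    """'congener', 'confamilial' or 'other' for two distinct species."""
    if taxonomy.nodes[a].parent == taxonomy.nodes[b].parent:
        return "congener"
    ga, gb = taxonomy.nodes[a].parent, taxonomy.nodes[b].parent
    if ga and gb and taxonomy.nodes[ga].parent == taxonomy.nodes[gb].parent:
        return "confamilial"
    return "other"


def simulate_hits(
    true_taxon: str,
    taxonomy: TaxonomyTable,
    identity_model: IdentityModel | None = None,
    n_references: int = 3,
    seed: int = 0,
    *,
    query_id: str = "q1",
    n_other: int = 5,
) -> list[Hit]:
    """Reference hits for one query whose DNA comes from ``true_taxon``.

    ``n_references`` identities are drawn uniformly within the intra-taxon
    range for the true species and within the rank-decayed range for every
    congener and confamilial species; ``n_other`` randomly chosen distant
    species get one draw each from the 'other' range.
    """
    model = identity_model or IdentityModel()
    if taxonomy.rank(true_taxon) != "species":
        raise ValidationError("true_taxon must be a species")
    rng = np.random.default_rng(seed)
    hits: list[Hit] = []

    def draw(taxon: str, rng_range: tuple[float, float], k: int) -> None:
        for ident in rng.uniform(*rng_range, size=k):
            hits.append(Hit(query_id, taxon, float(ident), 100.0, True))

    draw(true_taxon, model.intra, n_references)
    others = []
    for sp in taxonomy.species():
        if sp == true_taxon:
            continue
        rel = _relatedness(taxonomy, true_taxon, sp)
        if rel == "congener":
            draw(sp, model.congener, n_references)
        elif rel == "confamilial":
            draw(sp, model.confamilial, n_references)
        else:
            others.append(sp)
    if others and n_other > 0:
        chosen = rng.choice(others, size=min(n_other, len(others)), replace=False)
        for sp in chosen:
            draw(str(sp), model.other, 1)
    return hits


def simulate_hit_table(
    true_taxa: list[str],
    taxonomy: TaxonomyTable,
    identity_model: IdentityModel | None = None,
    n_references: int = 3,
    seed: int = 0,
    query_ids: list[str] | None = None,
) -> tuple[HitTable, dict[str, str]]:
    """Hit table for many queries with recorded truth (query id -> species)."""
    rng = np.random.default_rng(seed)
    if query_ids is not None and len(query_ids) != len(true_taxa):
        raise ValidationError("query_ids must match true_taxa in length")
    groups: dict[str, list[Hit]] = {}
    truth: dict[str, str] = {}
    for i, sp in enumerate(true_taxa):
        qid = query_ids[i] if query_ids is not None else f"asv{i + 1}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        groups[qid] = simulate_hits(
            sp, taxonomy, identity_model, n_references, sub_seed, query_id=qid
        )
        truth[qid] = sp
    return HitTable(groups), truth


# ---------------------------------------------------------------------------
# Community simulation
# ---------------------------------------------------------------------------


def _habitat_pools(
    species: list[str], config: SimulationConfig, rng: np.random.Generator
) -> dict[str, list[str]]:
    n_shared = round(config.overlap_fraction * config.pool_size)
    n_unique = config.pool_size - n_shared
    habs = habitat_names(config.n_habitats)
    needed = n_shared + config.n_habitats * n_unique
    if needed > len(species):
        raise ValidationError(
            f"pools need {needed} species but the taxonomy has {len(species)}"
        )
    order = rng.permutation(len(species))
    picked = [species[i] for i in order[:needed]]
    shared = picked[:n_shared]
    pools = {}
    for h, hab in enumerate(habs):
        start = n_shared + h * n_unique
        pools[hab] = sorted(shared + picked[start : start + n_unique])
    return pools


def simulate_community(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[ReplicateCountTable, dict[str, str], dict]:
    """Simulate the replicate read-count table of a multi-habitat survey.

    Returns (counts, sample metadata, truth).  Truth records the habitat
    pools, per-taxon community weights, and per-replicate detection masks.
    Column read sums equal ``reads_per_replicate`` exactly (multinomial
    allocation); the host taxon takes ``host_read_fraction`` of each
    replicate's reads in expectation.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    taxonomy = make_taxonomy(config.shape, include_host=True)
    species = sorted(sp for sp in taxonomy.species() if sp != HOST_TAXON_ID)
    pools = _habitat_pools(species, config, rng)
    union = sorted(set().union(*pools.values()))

    # Log-normal community weights.  The dominant taxon (a shared taxon if
    # any exist, so it spans habitats like the emulated study's top moth
    # fly) is rescaled to hold the configured share of the pools it
    # belongs to, averaged over those pools.
    weights = pd.Series(rng.lognormal(0.0, config.abundance_sigma, size=len(union)), index=union)
    shared = sorted(set.intersection(*(set(p) for p in pools.values())))
    top = weights[shared].idxmax() if shared else weights.idxmax()
    rest_per_pool = [
        weights[[t for t in pool if t != top]].sum()
        for pool in pools.values()
        if top in pool
    ]
    f = config.dominant_fraction
    weights[top] = f / (1.0 - f) * float(np.mean(rest_per_pool))

    habs = habitat_names(config.n_habitats)
    samples = []
    habitats: dict[str, str] = {}
    i = 0
    for hab in habs:
        for _ in range(config.samples_per_habitat):
            i += 1
            name = f"tx{i}"
            if name in config.dropped_samples:
                continue
            samples.append(name)
            habitats[name] = hab

    rows = union + [HOST_TAXON_ID]
    cols = pd.MultiIndex.from_tuples(
        [(s, f"r{r + 1}") for s in samples for r in range(config.replicates_per_sample)],
        names=["sample", "replicate"],
    )
    counts = pd.DataFrame(0, index=rows, columns=cols, dtype=np.int64)
    detection: dict[tuple[str, str], list[str]] = {}

    for s in samples:
        pool = pools[habitats[s]]
        w_pool = weights[pool]
        for r in range(config.replicates_per_sample):
            rep = f"r{r + 1}"
            detected = [t for t in pool if rng.random() < config.detection_prob]
            if not detected and config.host_read_fraction == 0.0:
                detected = [w_pool.idxmax()]  # keep the replicate non-empty
            detection[(s, rep)] = detected
            w = weights[detected].to_numpy() if detected else np.array([])
            hf = config.host_read_fraction
            if hf >= 1.0 or not w.size:
                taxa = [HOST_TAXON_ID]
                probs = np.array([1.0])
            elif hf > 0:
                host_w = hf / (1.0 - hf) * w.sum()
                taxa = detected + [HOST_TAXON_ID]
                probs = np.append(w, host_w)
            else:
                taxa = detected
                probs = w
            probs = probs / probs.sum()
            draw = rng.multinomial(config.reads_per_replicate, probs)
            counts.loc[taxa, (s, rep)] = draw
    table = ReplicateCountTable(counts, habitats)
    truth = {
        "pools": pools,
        "weights": weights,
        "detection": detection,
        "dominant_taxon": top,
        "taxonomy": taxonomy,
    }
    logger.info(
        "simulate_community: %d samples x %d replicates, %d taxa (+host), depth %d",
        len(samples), config.replicates_per_sample, len(union), config.reads_per_replicate,
    )
    return table, habitats, truth


# ---------------------------------------------------------------------------
# Monte-Carlo calibration of the differentiation test
# ---------------------------------------------------------------------------


def permanova_null_rejection_rate(
    n_sims: int = 500,
    n_samples: int = 9,
    n_groups: int = 3,
    n_permutations: int = 99,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the PERMANOVA permutation test: fraction of random
    distance matrices with uniformly random balanced group labels whose p
    falls at or below ``alpha``.  Should sit near ``alpha``."""
    from .ecostats import permanova
    from .io_core import DistanceMatrix

    rng = np.random.default_rng(seed)
    per = n_samples // n_groups
    base = [f"g{k}" for k in range(n_groups) for _ in range(per)]
    base += [f"g{k % n_groups}" for k in range(n_samples - len(base))]
    rejections = 0
    for _ in range(n_sims):
        m = rng.uniform(0.05, 1.0, size=(n_samples, n_samples))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        labels = rng.permutation(base)
        res = permanova(
            DistanceMatrix(m, [f"s{i}" for i in range(n_samples)]),
            labels, n_permutations, seed=int(rng.integers(2**31 - 1)),
        )
        rejections += res.p <= alpha
    return rejections / n_sims


def permanova_power_planted_effect(
    n_sims: int = 200,
    config: SimulationConfig | None = None,
    n_permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Power of Raup-Crick + PERMANOVA against the generator's default
    planted habitat effect (habitat-specific taxon pools): fraction of
    simulated surveys whose habitat test rejects at ``alpha``.

    With ``overlap_fraction = 1.0`` the pools coincide, the effect
    vanishes, and this same estimate returns to ~``alpha``.
    """
    from .ecostats import permanova, raup_crick
    from .io_core import CommunityMatrix

    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        counts, habitats, _ = simulate_community(
            replace(config, seed=int(rng.integers(2**31 - 1)))
        )
        pres = presence_from_counts(counts, exclude={HOST_TAXON_ID})
        cm = CommunityMatrix(pres, habitats)
        res = permanova(
            raup_crick(cm), cm.group_labels(), n_permutations,
            seed=int(rng.integers(2**31 - 1)),
        )
        rejections += res.p <= alpha
    return rejections / n_sims


def presence_from_counts(counts: ReplicateCountTable, exclude: set[str] = frozenset()):
    """Sample x taxon presence data frame (reads in any replicate), with
    optional taxa (e.g., the host) excluded."""
    per_sample = counts.counts.T.groupby(level="sample").sum().T
    pres = (per_sample > 0).astype(int).T  # sample x taxon
    keep = [t for t in pres.columns if t not in exclude]
    return pres[keep]
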