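"""Taxonomic assignment of ASVs from reference hits.

The rule chain, per query:

1. Discard hits below the identity / query-coverage floors, and hits that
   do not cover the query fully.
2. Summarise the surviving hits as a per-taxon identity range
   [min, max] over that taxon's reference sequences.
3. Candidate taxa: take the taxon (or taxa) achieving the single best
   identity; let m be the smallest of their range minima; every taxon whose
   range maximum reaches m is a candidate.  This captures the situation
   where the best-matching species itself has reference sequences matching
   down to, say, 98.5% — any other taxon matching at >= 98.5% cannot be
   excluded.
4. Collapse the candidates to their lowest common ancestor (LCA).
5. Cap the assignment rank by the best identity: species needs >= 98% and
   an unambiguous (singleton) candidate set; genus needs >= 91%; family
   needs >= 83%; below that the assignment is demoted to order and flagged
   low-confidence.  If the cap is more inclusive than the LCA's rank, the
   assignment moves up to the LCA's ancestor at the capped rank and is
   flagged ``demoted``.

Identities are compared exactly, with no rounding; ties are genuine ties.
"""

from __future__ import annotations

import logging

from .io_core import (
    RANK_DEPTH,
    Assignment,
    Hit,
    HitTable,
    TaxonomyTable,
    Thresholds,
    ValidationError,
)

logger = logging.getLogger("dungdna")


def filter_hits(hits: HitTable, thresholds: Thresholds) -> HitTable:
    """Apply the identity / coverage / full-coverage floors per hit.

    Queries left with no surviving hits remain in the table as empty
    groups, so no query silently disappears.
    """
    out: dict[str, list[Hit]] = {}
    n_in = n_kept = 0
    for query, group in hits:
        kept = [
            h
            for h in group
            if h.identity >= thresholds.min_identity
            and h.query_coverage >= thresholds.min_query_coverage
            and h.covers_query_fully
        ]
        n_in += len(group)
        n_kept += len(kept)
        out[query] = kept
    logger.info(
        "filter_hits: kept %d/%d hits (min identity %.1f%%, min coverage %.1f%%)",
        n_kept, n_in, thresholds.min_identity, thresholds.min_query_coverage,
    )
    return HitTable(out)


def taxon_identity_ranges(hits_for_query: list[Hit]) -> dict[str, tuple[float, float]]:
    """Per-taxon (min, max) of percent identity over that taxon's hits."""
    ranges: dict[str, tuple[float, float]] = {}
    for h in hits_for_query:
        lo, hi = ranges.get(h.subject_taxon_id, (h.identity, h.identity))
        ranges[h.subject_taxon_id] = (min(lo, h.identity), max(hi, h.identity))
    return ranges


def candidate_taxa(
    ranges: dict[str, tuple[float, float]], thresholds: Thresholds | None = None
) -> set[str]:
    """Taxa whose identity range overlaps that of the best-matching taxon.

    Let B be the set of taxa achieving the global maximum identity and m the
    minimum over B of their range minima; the candidates are every taxon
    whose range maximum is >= m.  Always contains B.
    """
    if not ranges:
        return set()
    best = max(hi for _, hi in ranges.values())
    best_taxa = {t for t, (_, hi) in ranges.items() if hi == best}
    m = min(ranges[t][0] for t in best_taxa)
    return {t for t, (_, hi) in ranges.items() if hi >= m}


def lowest_common_ancestor(taxa: set[str], taxonomy: TaxonomyTable) -> str:
    """Deepest taxonomy node that is ancestor-or-self of every input taxon."""
    if not taxa:
        raise ValidationError("LCA of an empty taxon set is undefined")
    common: set[str] | None = None
    for t in taxa:
        anc = taxonomy.ancestors_or_self(t)
        common = anc if common is None else common & anc
    assert common  # the root is always shared
    return max(common, key=lambda tid: RANK_DEPTH[taxonomy.rank(tid)])


def _identity_permitted_rank(
    best_identity: float, no_overlap: bool, thresholds: Thresholds
) -> tuple[str, bool]:
    """(most-exclusive rank the identity permits, low-confidence flag)."""
    if best_identity >= thresholds.species_threshold and no_overlap:
        return "species", False
    if best_identity >= thresholds.genus_threshold:
        return "genus", False
    if best_identity >= thresholds.family_threshold:
        return "family", False
    return "order", True  # below the family floor: order-level, low confidence


def apply_rank_thresholds(
    lca: str,
    best_identity: float,
    no_overlap: bool,
    taxonomy: TaxonomyTable,
    thresholds: Thresholds,
    *,
    query_id: str = "",
    candidates: frozenset[str] = frozenset(),
) -> Assignment:
    """Combine the LCA with the identity-permitted rank cap.

    The final rank is the more inclusive of the LCA's rank and the cap; if
    that moves the assignment above the LCA, the LCA's ancestor at the final
    rank is used and the assignment is flagged demoted.  An LCA above
    kingdom (i.e., the root) yields an unassigned record.
    """
    if lca not in taxonomy:
        raise ValidationError(f"unknown LCA taxon id {lca!r}")
    lca_rank = taxonomy.rank(lca)
    if RANK_DEPTH[lca_rank] < RANK_DEPTH["kingdom"]:
        return Assignment(query_id, None, None, best_identity, candidates)

    permitted, low_conf = _identity_permitted_rank(best_identity, no_overlap, thresholds)
    if RANK_DEPTH[permitted] >= RANK_DEPTH[lca_rank]:
        # LCA governs; identity permits at least this much resolution.
        return Assignment(query_id, lca, lca_rank, best_identity, candidates,
                          demoted=False, low_confidence=low_conf)
    target = taxonomy.ancestor_at_rank(lca, permitted)
    if target is None:
        # Lineage skips the capped rank; take the nearest more-inclusive
        # ancestor below the cap's depth.
        for tid in taxonomy.path_to_root(lca):
            if RANK_DEPTH[taxonomy.rank(tid)] <= RANK_DEPTH[permitted]:
                target = tid
                break
    if target is None or RANK_DEPTH[taxonomy.rank(target)] < RANK_DEPTH["kingdom"]:
        return Assignment(query_id, None, None, best_identity, candidates)
    return Assignment(query_id, target, taxonomy.rank(target), best_identity,
                      candidates, demoted=True, low_confidence=low_conf)


def assign_one(
    query_id: str,
    hits_for_query: list[Hit],
    taxonomy: TaxonomyTable,
    thresholds: Thresholds,
) -> Assignment:
    """Assignment for one query from its already-filtered hits."""
    if not hits_for_query:
        return Assignment(query_id, None, None, None)
    ranges = taxon_identity_ranges(hits_for_query)
    cands = candidate_taxa(ranges, thresholds)
    best = max(hi for _, hi in ranges.values())
    best_taxa = {t for t, (_, hi) in ranges.items() if hi == best}
    no_overlap = cands == best_taxa and len(best_taxa) == 1
    lca = lowest_common_ancestor(cands, taxonomy)
    return apply_rank_thresholds(
        lca, best, no_overlap, taxonomy, thresholds,
        query_id=query_id, candidates=frozenset(cands),
    )


def assign_all(
    hits: HitTable, taxonomy: TaxonomyTable, thresholds: Thresholds | None = None
) -> list[Assignment]:
    """Filter hits and assign every query; unassigned queries are emitted
    (never dropped) so read accounting is conserved downstream."""
    thresholds = thresholds or Thresholds()
    filtered = filter_hits(hits, thresholds)
    out = [
        assign_one(query, group, taxonomy, thresholds)
        for query, group in filtered
    ]
    n_assigned = sum(a.assigned for a in out)
    logger.info("assign_all: %d/%d queries assigned", n_assigned, len(out))
    return out
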