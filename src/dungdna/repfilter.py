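"""PCR-replicate consistency filtering and the final taxon table.

Detections supported by a single PCR replicate across the whole data set
are treated as likely artefacts (polymerase error, low-level contamination,
tag jumps) and removed; host (cow) reads are removed; ASVs assigned to the
same final taxon are pooled.  What remains is the "final taxon table":
per-taxon lineage, habitat presence flags, and total reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import (
    Assignment,
    CommunityMatrix,
    ReplicateCountTable,
    TaxonomyTable,
    Thresholds,
    ValidationError,
)

logger = logging.getLogger("dungdna")


def replicate_support(counts: ReplicateCountTable) -> pd.Series:
    """Number of PCR replicate columns (across ALL samples) in which each
    taxon has at least one read.

    Support is counted data-set-wide: a taxon seen once in sample A's first
    replicate and once in sample B's second replicate has support 2.
    """
    return (counts.counts > 0).sum(axis=1)


def replicate_support_per_sample(counts: ReplicateCountTable) -> pd.Series:
    """Maximum within-sample replicate support per taxon (optional stricter
    mode: a taxon must repeat within a single sample)."""
    return counts.counts.gt(0).T.groupby(level="sample").sum().T.max(axis=1)


@dataclass
class FinalTaxonTable:
    """Retained taxa with habitat presence flags and pooled read totals."""

    table: pd.DataFrame  # index taxon_id; columns: rank, name, habitat flags..., reads
    habitats: list[str]
    dropped: pd.DataFrame = field(default_factory=pd.DataFrame)  # accounting sidecar

    @property
    def taxa(self) -> list[str]:
        return list(self.table.index)

    def total_reads(self) -> int:
        return int(self.table["reads"].sum())

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")


def filter_final(
    counts: ReplicateCountTable,
    assignments: list[Assignment],
    thresholds: Thresholds | None = None,
    host_taxa: set[str] = frozenset(),
    taxonomy: TaxonomyTable | None = None,
    *,
    per_sample_support: bool = False,
) -> FinalTaxonTable:
    """Produce the final taxon table from replicate counts and assignments.

    Drops unassigned ASVs, host taxa, and taxa below the replicate-support
    floor; pools ASVs assigned to the same taxon; computes habitat presence
    flags from retained reads.  Every dropped read is accounted for in the
    ``dropped`` sidecar so totals are conserved exactly.
    """
    thresholds = thresholds or Thresholds()
    by_query = {a.query_id: a for a in assignments}
    missing = [t for t in counts.taxa if t not in by_query]
    if missing:
        raise ValidationError(f"count rows without an assignment: {missing[:5]}")

    # 1. map ASVs to final taxa (None = unassigned)
    asv_taxon = {t: by_query[t].taxon_id for t in counts.taxa}

    # 2. pool ASV rows by assigned taxon
    pooled: dict[str, np.ndarray] = {}
    dropped_rows = []
    for asv in counts.taxa:
        row = counts.counts.loc[asv].to_numpy()
        taxon = asv_taxon[asv]
        if taxon is None:
            dropped_rows.append((asv, "unassigned", int(row.sum())))
            continue
        pooled[taxon] = pooled.get(taxon, np.zeros(counts.counts.shape[1], dtype=np.int64)) + row
    pooled_df = pd.DataFrame(pooled, index=counts.counts.columns).T
    pooled_df.columns = counts.counts.columns

    # 3. host removal, then replicate support on the pooled taxa
    keep = []
    if len(pooled_df):
        pooled_table = ReplicateCountTable(pooled_df, counts.habitats)
        support = (
            replicate_support_per_sample(pooled_table)
            if per_sample_support
            else replicate_support(pooled_table)
        )
        for taxon in pooled_df.index:
            total = int(pooled_df.loc[taxon].sum())
            if taxon in host_taxa:
                dropped_rows.append((taxon, "host", total))
            elif int(support[taxon]) < thresholds.min_replicates:
                dropped_rows.append((taxon, "low_replicate_support", total))
            else:
                keep.append(taxon)

    kept = pooled_df.loc[keep]
    habitats = sorted(set(counts.habitats[s] for s in counts.samples))
    rows = {}
    sample_habitat = counts.habitats
    col_habitat = np.array([sample_habitat[s] for s, _ in kept.columns]) if len(keep) else np.array([])
    for taxon in keep:
        row = kept.loc[taxon].to_numpy()
        entry: dict[str, object] = {}
        if taxonomy is not None and taxon in taxonomy:
            entry["rank"] = taxonomy.rank(taxon)
            entry["name"] = taxonomy.name(taxon)
        for hab in habitats:
            entry[hab] = bool(row[col_habitat == hab].sum() > 0)
        entry["reads"] = int(row.sum())
        rows[taxon] = entry
    table = pd.DataFrame.from_dict(rows, orient="index")
    if table.empty:
        cols = ["reads"] + habitats
        table = pd.DataFrame(columns=cols).astype({"reads": np.int64})
    dropped = pd.DataFrame(dropped_rows, columns=["id", "reason", "reads"])
    logger.info(
        "filter_final: retained %d taxa (%d reads); dropped %d rows (%d reads)",
        len(table), int(table["reads"].sum()) if len(table) else 0,
        len(dropped), int(dropped["reads"].sum()) if len(dropped) else 0,
    )
    return FinalTaxonTable(table=table, habitats=habitats, dropped=dropped)


def final_table_to_community(
    counts: ReplicateCountTable, final: FinalTaxonTable, assignments: list[Assignment]
) -> CommunityMatrix:
    """Sample x taxon presence matrix restricted to retained taxa."""
    by_query = {a.query_id: a for a in assignments}
    data = pd.DataFrame(
        0, index=counts.samples, columns=final.taxa, dtype=np.int64
    )
    for asv in counts.taxa:
        taxon = by_query[asv].taxon_id
        if taxon in final.taxa:
            per_sample = counts.counts.loc[asv].groupby(level="sample").sum()
            data.loc[per_sample.index, taxon] += per_sample.to_numpy()
    habitats = {s: counts.habitats[s] for s in counts.samples}
    return CommunityMatrix(data, habitats)


def read_fraction_summary(final: FinalTaxonTable | pd.DataFrame, k: int) -> tuple[float, pd.Series]:
    """(fraction of total reads in the k most abundant taxa, per-taxon
    fractions).  Fractions are of the table's own read total, in [0, 1]."""
    reads = final["reads"] if isinstance(final, pd.DataFrame) else final.table["reads"]
    if len(reads) == 0:
        raise ValidationError("read_fraction_summary on an empty table")
    if k > len(reads):
        logger.warning("read_fraction_summary: k=%d > %d taxa; truncating", k, len(reads))
        k = len(reads)
    total = reads.sum()
    fractions = (reads / total).sort_values(ascending=False)
    return float(fractions.iloc[:k].sum()), fractions


def blank_report(counts: ReplicateCountTable, blank_label: str = "blank") -> pd.Series:
    """Total retained reads per blank (control) sample; no subtraction is
    applied — blanks are reported, not used to correct samples."""
    blanks = [s for s in counts.samples if counts.habitats[s] == blank_label]
    return pd.Series(
        {s: int(counts.counts.loc[:, s].to_numpy().sum()) for s in blanks}, dtype=np.int64
    )


# -- richness summaries on a lineage-annotated table (packaged-fixture shape) --


def richness_by_rank(table: pd.DataFrame, na_label: str = "NA") -> dict[str, int]:
    """Distinct named orders/families and species-resolution counts for a
    final taxon table carrying class/order/family/final_identification
    columns (rows named '<Genus> sp.' or '<Order> sp.' are unresolved).

    Unresolved rows are excluded from counts of ranks below their own
    resolution: a family-NA row contributes to order richness only.
    """
    orders = {o for o in table["order"] if o != na_label}
    families = {f for f in table["family"] if f != na_label}
    unresolved = table["final_identification"].str.endswith(" sp.")
    return {
        "orders": len(orders),
        "families": len(families),
        "species": int((~unresolved).sum()),
        "unresolved_to_species": int(unresolved.sum()),
    }
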