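"""Domain types and tabular I/O shared by every pipeline stage.

The pipeline's substrate is small and tabular throughout: a rank-labelled
taxonomy, per-query reference hits with percent identity and coverage, a
taxon x (sample, PCR-replicate) read-count matrix, and symmetric sample
dissimilarity matrices.  All files are plain TSV; dendrograms are Newick.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("dungdna")

# Ranks from most to least inclusive. Index in this tuple is "depth":
# larger depth means less inclusive (closer to the tips).
RANKS: tuple[str, ...] = (
    "root",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

RANK_DEPTH: dict[str, int] = {r: i for i, r in enumerate(RANKS)}


class ParseError(ValueError):
    """A malformed input row; message names the offending line number."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaxonNode:
    name: str
    rank: str
    parent: str | None  # None only for the root


class TaxonomyTable:
    """Rooted, rank-labelled taxonomy: substrate for LCA and rank demotion.

    Invariants checked at construction: exactly one root, every parent id
    resolves, no cycles, and rank depth strictly increases away from the
    root along every parent-child edge.
    """

    def __init__(self, nodes: Mapping[str, TaxonNode]):
        self.nodes: dict[str, TaxonNode] = dict(nodes)
        self._validate()

    def _validate(self) -> None:
        roots = [tid for tid, n in self.nodes.items() if n.parent is None]
        if len(roots) != 1:
            raise ValidationError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        if self.nodes[self.root].rank != "root":
            raise ValidationError("root node must have rank 'root'")
        for tid, node in self.nodes.items():
            if node.rank not in RANK_DEPTH:
                raise ValidationError(f"unknown rank {node.rank!r} for taxon {tid!r}")
            if node.parent is None:
                continue
            if node.parent not in self.nodes:
                raise ValidationError(f"taxon {tid!r} has unresolved parent {node.parent!r}")
            if RANK_DEPTH[self.nodes[node.parent].rank] >= RANK_DEPTH[node.rank]:
                raise ValidationError(
                    f"rank must strictly decrease toward the root: {tid!r} "
                    f"({node.rank}) under {node.parent!r} ({self.nodes[node.parent].rank})"
                )
        # Acyclicity: every node must reach the root.
        for tid in self.nodes:
            seen = set()
            cur: str | None = tid
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cycle detected through taxon {tid!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def rank(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].rank

    def name(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].name

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Taxon ids from ``taxon_id`` up to and including the root."""
        if taxon_id not in self.nodes:
            raise ValidationError(f"unknown taxon id {taxon_id!r}")
        path = [taxon_id]
        while (parent := self.nodes[path[-1]].parent) is not None:
            path.append(parent)
        return path

    def ancestors_or_self(self, taxon_id: str) -> set[str]:
        return set(self.path_to_root(taxon_id))

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """The ancestor-or-self of ``taxon_id`` at ``rank``, or None if the
        lineage skips that rank."""
        for tid in self.path_to_root(taxon_id):
            if self.nodes[tid].rank == rank:
                return tid
        return None

    def species(self) -> list[str]:
        return [tid for tid, n in self.nodes.items() if n.rank == "species"]

    # -- I/O: 4-column TSV (id, parent, rank, name); empty parent = root --

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"id", "parent", "rank", "name"}
        if not required.issubset(df.columns):
            raise ParseError(f"taxonomy file must have columns {sorted(required)}")
        nodes = {}
        for row in df.itertuples(index=False):
            parent = row.parent if row.parent != "" else None
            nodes[row.id] = TaxonNode(name=row.name, rank=row.rank, parent=parent)
        if len(nodes) != len(df):
            raise ValidationError("duplicate taxon ids in taxonomy file")
        return cls(nodes)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"id": tid, "parent": n.parent or "", "rank": n.rank, "name": n.name}
            for tid, n in self.nodes.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Hit:
    """One reference-database hit for a query ASV."""

    query_id: str
    subject_taxon_id: str
    identity: float  # percent in [0, 100]
    query_coverage: float  # percent in [0, 100]
    covers_query_fully: bool = True

    def __post_init__(self):
        if not (0.0 <= self.identity <= 100.0):
            raise ValidationError(f"identity {self.identity} outside [0, 100]")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValidationError(f"query coverage {self.query_coverage} outside [0, 100]")


class HitTable:
    """Reference hits grouped by query id; grouping is exhaustive and disjoint.

    Queries whose hits are all removed by filtering stay present with an
    empty group, so read accounting downstream is conserved.
    """

    def __init__(self, groups: Mapping[str, Sequence[Hit]]):
        self.groups: dict[str, list[Hit]] = {q: list(hits) for q, hits in groups.items()}
        for query, hits in self.groups.items():
            for h in hits:
                if h.query_id != query:
                    raise ValidationError(
                        f"hit with query id {h.query_id!r} grouped under {query!r}"
                    )

    @classmethod
    def from_hits(cls, hits: Iterable[Hit]) -> "HitTable":
        groups: dict[str, list[Hit]] = {}
        for h in hits:
            groups.setdefault(h.query_id, []).append(h)
        return cls(groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __iter__(self) -> Iterator[tuple[str, list[Hit]]]:
        return iter(self.groups.items())

    def n_hits(self) -> int:
        return sum(len(v) for v in self.groups.values())


#: Column names accepted in hit-table TSVs (BLAST outfmt-6 style extensions).
HIT_COLUMNS = ("qseqid", "staxid", "pident", "qcovhsp", "full_coverage")

_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


def read_hit_table(path: str | Path, taxonomy: TaxonomyTable) -> HitTable:
    """Read a tab-separated hit table with header columns qseqid, staxid,
    pident, qcovhsp and an optional full_coverage flag (default true).

    Malformed rows raise :class:`ParseError` naming the line number; rows
    whose subject taxon is absent from ``taxonomy`` raise
    :class:`ValidationError` listing every unknown id.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise ParseError(f"{path}: missing header line")
        header = header_line.rstrip("\n").split("\t")
        for col in ("qseqid", "staxid", "pident", "qcovhsp"):
            if col not in header:
                raise ParseError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in header}
        has_flag = "full_coverage" in idx

        hits: list[Hit] = []
        unknown: set[str] = set()
        n_rows = 0
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            n_rows += 1
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}")
            try:
                pident = float(fields[idx["pident"]])
                qcov = float(fields[idx["qcovhsp"]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric identity/coverage") from exc
            if has_flag:
                raw = fields[idx["full_coverage"]].strip().lower()
                if raw in _TRUTHY:
                    full = True
                elif raw in _FALSY:
                    full = False
                else:
                    raise ParseError(f"{path}:{lineno}: bad full_coverage value {raw!r}")
            else:
                full = True
            staxid = fields[idx["staxid"]]
            if staxid not in taxonomy:
                unknown.add(staxid)
                continue
            try:
                hits.append(
                    Hit(
                        query_id=fields[idx["qseqid"]],
                        subject_taxon_id=staxid,
                        identity=pident,
                        query_coverage=qcov,
                        covers_query_fully=full,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    if unknown:
        raise ValidationError(f"{path}: unknown taxon ids: {sorted(unknown)}")
    table = HitTable.from_hits(hits)
    logger.info("read_hit_table: %d rows, %d queries from %s", n_rows, len(table), path)
    return table


def write_hit_table(table: HitTable, path: str | Path) -> None:
    rows = [
        {
            "qseqid": h.query_id,
            "staxid": h.subject_taxon_id,
            "pident": h.identity,
            "qcovhsp": h.query_coverage,
            "full_coverage": int(h.covers_query_fully),
        }
        for _, hits in table
        for h in hits
    ]
    pd.DataFrame(rows, columns=list(HIT_COLUMNS)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Thresholds:
    """Pipeline-wide tuning constants.

    Identity cut-offs are percent sequence similarity against the reference
    database: hits below ``min_identity`` or ``min_query_coverage`` are
    discarded, and the best retained identity caps the assignment rank at
    species (>= 98), genus (>= 91) or family (>= 83).
    """

    min_identity: float = 80.0
    min_query_coverage: float = 90.0
    species_threshold: float = 98.0
    genus_threshold: float = 91.0
    family_threshold: float = 83.0
    min_replicates: int = 2
    n_permutations: int = 999
    cube_exponent: float = 1.0 / 3.0

    def __post_init__(self):
        if not (0 <= self.family_threshold < self.genus_threshold < self.species_threshold <= 100):
            raise ValidationError("rank thresholds must satisfy 0 <= family < genus < species <= 100")
        if self.min_replicates < 1:
            raise ValidationError("min_replicates must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Assignment:
    """Outcome of taxonomic assignment for one query ASV."""

    query_id: str
    taxon_id: str | None  # None = unassigned
    rank: str | None
    best_identity: float | None
    candidate_taxa: frozenset[str] = frozenset()
    demoted: bool = False
    low_confidence: bool = False

    @property
    def assigned(self) -> bool:
        return self.taxon_id is not None


ASSIGNMENT_COLUMNS = (
    "query_id",
    "taxon_id",
    "rank",
    "best_identity",
    "candidate_taxa",
    "demoted",
    "low_confidence",
)


def write_assignments(assignments: Sequence[Assignment], path: str | Path) -> None:
    rows = [
        {
            "query_id": a.query_id,
            "taxon_id": a.taxon_id or "",
            "rank": a.rank or "",
            "best_identity": "" if a.best_identity is None else a.best_identity,
            "candidate_taxa": ";".join(sorted(a.candidate_taxa)),
            "demoted": int(a.demoted),
            "low_confidence": int(a.low_confidence),
        }
        for a in assignments
    ]
    pd.DataFrame(rows, columns=list(ASSIGNMENT_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> list[Assignment]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            Assignment(
                query_id=row.query_id,
                taxon_id=row.taxon_id or None,
                rank=row.rank or None,
                best_identity=float(row.best_identity) if row.best_identity else None,
                candidate_taxa=frozenset(t for t in row.candidate_taxa.split(";") if t),
                demoted=bool(int(row.demoted)),
                low_confidence=bool(int(row.low_confidence)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Replicate count table
# ---------------------------------------------------------------------------


class ReplicateCountTable:
    """Taxon/ASV x (sample, PCR replicate) read counts plus sample habitats.

    ``counts`` has a two-level column MultiIndex (sample, replicate);
    ``habitats`` maps sample id -> habitat label. Blank (control) samples are
    ordinary columns whose habitat label identifies them as blanks.
    """

    def __init__(self, counts: pd.DataFrame, habitats: Mapping[str, str]):
        if counts.columns.nlevels != 2:
            raise ValidationError("counts must have (sample, replicate) column MultiIndex")
        if counts.columns.duplicated().any():
            raise ValidationError("duplicate (sample, replicate) columns")
        if counts.index.duplicated().any():
            raise ValidationError("duplicate taxon row labels")
        if (counts.to_numpy() < 0).any():
            raise ValidationError("negative read counts")
        self.counts = counts.astype(np.int64)
        self.habitats = dict(habitats)
        missing = set(counts.columns.get_level_values(0)) - set(self.habitats)
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.counts.columns.get_level_values(0)))

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ReplicateCountTable)
            and self.counts.equals(other.counts)
            and self.habitats == other.habitats
        )


def read_count_table(path: str | Path, metadata_path: str | Path) -> ReplicateCountTable:
    """Read a taxon x sample_replicate count TSV plus a sample metadata TSV.

    Count columns are named ``<sample>_<replicate>`` (split on the last
    underscore); metadata has columns ``sample`` and ``habitat``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.columns.duplicated().any():
        raise ValidationError(f"{path}: duplicate column labels")
    pairs = []
    for col in df.columns:
        if "_" not in col:
            raise ParseError(f"{path}: column {col!r} is not of the form sample_replicate")
        sample, rep = col.rsplit("_", 1)
        pairs.append((sample, rep))
    counts = df.copy()
    counts.columns = pd.MultiIndex.from_tuples(pairs, names=["sample", "replicate"])
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample", "habitat"}.issubset(meta.columns):
        raise ParseError(f"{metadata_path}: metadata needs 'sample' and 'habitat' columns")
    habitats = dict(zip(meta["sample"], meta["habitat"]))
    table = ReplicateCountTable(counts, habitats)
    logger.info(
        "read_count_table: %d taxa x %d replicate columns (%d samples) from %s",
        len(table.taxa), counts.shape[1], len(table.samples), path,
    )
    return table


def write_count_table(
    table: ReplicateCountTable, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    flat = table.counts.copy()
    flat.columns = [f"{s}_{r}" for s, r in table.counts.columns]
    flat.index.name = "taxon"
    flat.to_csv(path, sep="\t")
    if metadata_path is not None:
        pd.DataFrame(
            {"sample": list(table.habitats), "habitat": list(table.habitats.values())}
        ).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Community matrix
# ---------------------------------------------------------------------------


class CommunityMatrix:
    """Sample x taxon matrix (presence/absence or reads) with habitat labels."""

    def __init__(self, data: pd.DataFrame, habitats: Mapping[str, str] | None = None):
        if data.index.duplicated().any() or data.columns.duplicated().any():
            raise ValidationError("duplicate sample or taxon labels")
        empty = data.columns[(data.to_numpy() == 0).all(axis=0)]
        if len(empty):
            data = data.drop(columns=empty)
        self.data = data
        self.habitats = dict(habitats) if habitats is not None else {}
        missing = set(data.index) - set(self.habitats) if self.habitats else set()
        if missing:
            raise ValidationError(f"samples without habitat label: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    def presence(self) -> pd.DataFrame:
        return (self.data > 0).astype(int)

    def group_labels(self) -> np.ndarray:
        return np.array([self.habitats[s] for s in self.samples])

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "sample"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, metadata_path: str | Path | None = None) -> "CommunityMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        habitats = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
            habitats = dict(zip(meta["sample"], meta["habitat"]))
        return cls(data, habitats)


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a transform-provenance tag.

    The diagonal is stored as 0 by convention; downstream statistics never
    read it (for Raup-Crick, self-dissimilarity under the null is not 0).
    """

    values: np.ndarray
    labels: list[str]
    transform: str = "none"  # none | inverse-normal | cube-root

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValidationError("label count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if (v < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        if np.isnan(v).any():
            raise ValidationError("NaN entries in distance matrix")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def with_values(self, values: np.ndarray, transform: str | None = None) -> "DistanceMatrix":
        return DistanceMatrix(values, list(self.labels), transform or self.transform)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.index.name = f"#transform={self.transform}"
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        tag = "none"
        if df.index.name and df.index.name.startswith("#transform="):
            tag = df.index.name.split("=", 1)[1]
        return cls(df.to_numpy(dtype=float), list(df.columns), tag)


# ---------------------------------------------------------------------------
# Trophic map
# ---------------------------------------------------------------------------

TROPHIC_GROUPS = (
    "Coleoptera A",
    "Coleoptera B",
    "Diptera D",
    "Diptera E",
    "Diptera F",
    "Collembola",
    "Acari",
    "Dermaptera",
    "cow parasite",
    "nonspecific",
)


def validate_trophic_map(mapping: Mapping[str, str]) -> dict[str, str]:
    bad = {t: g for t, g in mapping.items() if g not in TROPHIC_GROUPS}
    if bad:
        raise ValidationError(f"unknown trophic group labels: {bad}")
    return dict(mapping)


def read_trophic_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"taxon", "group"}.issubset(df.columns):
        raise ParseError(f"{path}: trophic map needs 'taxon' and 'group' columns")
    return validate_trophic_map(dict(zip(df["taxon"], df["group"])))


# ---------------------------------------------------------------------------
# FASTA (identifier pass-through for ASV sequences)
# ---------------------------------------------------------------------------


def read_fasta_ids(path: str | Path) -> list[str]:
    """Sequence identifiers from a FASTA file, in file order."""
    ids = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                ids.append(line[1:].strip().split()[0])
    return ids


# ---------------------------------------------------------------------------
# Packaged fixture: the study's final taxon table
# ---------------------------------------------------------------------------

_TABLE1_PATH = Path(__file__).parent / "data" / "table1.tsv"


def load_table1() -> pd.DataFrame:
    """The packaged final taxon table of the cow-dung study: one row per
    retained taxon with class/order/family, final identification, habitat
    presence flags (grassland, meadow, forest) and total read count."""
    df = pd.read_csv(_TABLE1_PATH, sep="\t", dtype=str, keep_default_na=False)
    df["reads"] = df["reads"].astype(np.int64)
    for hab in ("grassland", "meadow", "forest"):
        df[hab] = df[hab] == "x"
    return df
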