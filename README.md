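# dungdna

Invertebrate communities living in and on herbivore dung can be surveyed
without catching a single animal: the dung itself carries traces of their
DNA. `dungdna` is a small analysis pipeline for COI metabarcoding of such
environmental DNA (eDNA) samples — for instance cow dung collected across
several habitats — taking the data from per-ASV reference-database hits and
per-PCR-replicate read counts all the way to a final taxon table and
habitat-level community statistics. It is aimed at molecular ecologists who
have already denoised their amplicon reads into ASVs (amplicon sequence
variants) and searched them against a reference database, and now need the
downstream steps to be reproducible and testable.

## What it does

**Taxonomic assignment** (`dungdna.taxassign`). Hits below 80% identity or
90% query coverage, or not covering the query fully, are discarded. For each
query the remaining hits are summarised as per-taxon identity ranges
[min, max]. Taxa whose range overlaps that of the best-matching taxon are
candidates: if the best taxon's own references span down to identity *m*,
every taxon matching at ≥ *m* is kept (a 99% best hit whose species also
matches at 98.5% pulls in a congener at 98.7%). Candidates collapse to their
lowest common ancestor, and the best identity caps the rank: species needs
≥ 98% with an unambiguous candidate set, genus ≥ 91%, family ≥ 83%; below
that the record drops to order and is flagged low-confidence.

**Replicate filtering** (`dungdna.repfilter`). Taxa detected in only a
single PCR replicate across the whole data set are removed as likely
artefacts; host (cow) reads are removed; ASVs assigned to the same taxon are
pooled. Read accounting is exact: every dropped read is reported in a
sidecar table.

**Community ecology** (`dungdna.ecostats`). Analytic rarefaction per
replicate, exact species accumulation over sites, Raup–Crick dissimilarity
from its hypergeometric null
(d = P(X ≥ j) for two samples with a and b taxa sharing j out of a pool of
S), one-way PERMANOVA with permutation p-values, a permutation test for
homogeneity of multivariate dispersions, rank-based inverse-normal and
cube-root distance transforms, UPGMA clustering with Newick export, richness
ANOVA, and trophic-group aggregation.

**Synthetic data** (`dungdna.synthdata`). A known-truth generator for every
input: a balanced taxonomy, habitat-specific taxon pools with configurable
overlap, log-normal abundances with a dominant taxon at 37% of reads, two
PCR replicates with detection dropout, multinomial read depths, host reads,
and hit tables drawn from per-rank identity ranges. It also provides
Monte-Carlo calibration of the PERMANOVA stage (type-I error and power
against the planted habitat effect).

## Worked example

```python
import dungdna as d

counts, habitats, truth = d.simulate_community(seed=31)
taxonomy = truth["taxonomy"]
hits, _ = d.simulate_hit_table(list(counts.taxa), taxonomy,
                               seed=32, query_ids=list(counts.taxa))
assignments = d.assign_all(hits, taxonomy)
final = d.filter_final(counts, assignments,
                       host_taxa={d.HOST_TAXON_ID}, taxonomy=taxonomy)
cm = d.final_table_to_community(counts, final, assignments)
dist = d.raup_crick(cm)
f_disp, p_disp = d.dispersion_test(dist, cm.group_labels(), 999, seed=33)
result = d.permanova(d.inverse_normal_distances(dist),
                     cm.group_labels(), 999, seed=34)
print(len(final.taxa), final.total_reads())
print(f"dispersion homogeneity: F = {f_disp:.4f}, p = {p_disp:.4f}")
print(result.report())
```

prints

```
59 512678
dispersion homogeneity: F = 1.3054, p = 0.4480
PERMANOVA: pseudo-F = 43.2454, R2 = 0.9453, p = 0.0050 (999 permutations)
```

— 59 taxa survive assignment, host removal and the two-replicate rule,
keeping 512,678 of the 640,000 simulated reads. Group dispersions are
homogeneous (p = 0.45), and the PERMANOVA on inverse-normal-transformed
Raup–Crick distances attributes ~95% of the between-sample variation to
habitat with a permutation p of 0.005 — recovering the habitat structure
the generator planted.

The same steps are available from a shell via the `dungdna` CLI
(`simulate`, `assign`, `filter`, `ecology`, `table1`).

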