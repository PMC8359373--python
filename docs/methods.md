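# Methods

This note documents the models and procedures implemented in `dungdna`,
their assumptions, the parameters that matter, and the deliberate design
choices made where the methodology was genuinely open.

## Taxonomic assignment

The assignment operates on percent-identity hits of each ASV against a
reference database, never on sequences. Its premise is that a reference
taxon is rarely represented by a single sequence: the same species may
match one query at 99% through one voucher and 98.5% through another. A
point estimate of "the" identity of a taxon is therefore replaced by the
per-taxon identity **range** [min, max] over that taxon's retained hits.

Steps, per query:

1. **Hit filtering.** Keep hits with identity ≥ `min_identity` (default
   80%), query coverage ≥ `min_query_coverage` (default 90%), and a true
   full-coverage flag. The flag is an input property of each hit rather
   than a numeric rule, because "complete final coverage" depends on how
   the upstream search merged high-scoring segment pairs; callers who do
   not track it can leave it true.
2. **Candidate selection.** Let B be the taxa achieving the single best
   identity and m the smallest range-minimum among B. Every taxon whose
   range-maximum reaches m is a candidate. When several taxa tie for the
   best identity, m is the minimum over all of them — the most inclusive
   reading, chosen because it is symmetric in the tied taxa and
   deterministic.
3. **LCA collapse.** Candidates are replaced by their lowest common
   ancestor in the rank-labelled taxonomy.
4. **Rank capping.** The best identity caps the attainable rank: species
   at ≥ 98%, genus at ≥ 91%, family at ≥ 83% (all configurable through
   `Thresholds`). Species additionally requires "no overlap": the
   candidate set must be exactly one taxon. A singleton candidate set is
   taken to satisfy the no-overlap condition — the natural contrast is
   between an ambiguous candidate set and a single clear best taxon, not
   between hit-count configurations. If the cap is more inclusive than
   the LCA's rank, the assignment moves to the LCA's ancestor at the
   capped rank and is flagged `demoted`.

Below the family floor no standard rule exists; such records are demoted
to the order-level ancestor and flagged `low_confidence` rather than
discarded, mirroring real final tables that contain order-level rows.
Identities are compared exactly as given, with no rounding: ties are
genuine ties, and no hidden precision policy can flip a candidate in or
out of the set. Unassigned queries are always emitted with a flag so read
accounting downstream stays exact.

## Replicate filtering

A detection supported by a single PCR replicate anywhere in the data set
is treated as unreliable (PCR/sequencing error, low-level contamination)
and removed: support is the number of replicate columns, across **all**
samples, with at least one read (default floor 2). A stricter per-sample
mode (`per_sample_support=True`) requiring repetition within one sample
is provided but is not the default. ASVs mapping to the same final taxon
are pooled **before** the support check, since the unit of biological
interest is the taxon. Host taxa are removed by id. Presence is read
count > 0 with no additional abundance floor — none is assumed by the
model, and any such floor would interact with the replicate rule in
untestable ways. Blank (control) samples ride through as ordinary columns
flagged by their metadata label; their retained reads are reported, never
subtracted.

## Rarefaction and accumulation

Both curves are exact hypergeometric expectations rather than resampling
means. For reads: E[S_n] = Σ_i [1 − C(N−N_i, n)/C(N, n)]. For sites:
S(t) = Σ_i [1 − C(T−T_i, t)/C(T, t)]. Binomial coefficients are evaluated
through log-gamma, so depths of 10⁵–10⁶ reads are handled without
overflow; terms with C(N−N_i, n) undefined (taxon cannot be missed)
contribute exactly 1. The accumulation SD is estimated by resampling
random site orderings (default 1000, seeded) because the closed-form
unconditional variance adds complexity without changing any inference
drawn here; the curves' confidence envelopes are qualitative.

## Raup–Crick dissimilarity

For two samples holding a and b taxa of a pool of S, sharing j, the
dissimilarity is the null tail probability d = P(X ≥ j) with X
hypergeometric (draw b from S with a marked). Conventions fixed here:

- **Tail direction**: d is small when samples share *more* than chance and
  exactly 1 for disjoint samples. Descriptions of this index in the
  literature ("1 − prob") are ambiguous about which tail and whether the
  observed j is included; this implementation fixes P(X ≥ j), documents
  it, and validates it against both exhaustive enumeration and a
  Monte-Carlo null. Numerical equality with any particular package's
  variant is deliberately not claimed.
- **Species pool**: the taxa present in ≥ 1 sample of the analyzed
  matrix. No regional pool is assumed, and occurrence-frequency-weighted
  null sampling (an alternative null some packages offer) is not used.
- **Degenerate cases**: empty samples and samples spanning the whole pool
  make the null degenerate; they are accepted with a warning and yield
  d = 1 from the tail formula.

Distance matrices are stored in full symmetric form with a 0 diagonal by
convention, although the Raup–Crick self-comparison under the null is not
0; no downstream statistic reads the diagonal.

## PERMANOVA, dispersions, transforms

One-way PERMANOVA partitions squared dissimilarities:
SS_total = (1/n)·Σ_{i<j} d²_ij, SS_within = Σ_g (1/n_g)·Σ_{i<j∈g} d²_ij,
pseudo-F = (SS_between/(a−1))/(SS_within/(n−a)), R² = SS_between/SS_total.
p-values use random label permutations with the add-one estimator
(1 + #{F* ≥ F})/(1 + m), which is never anti-conservative. R² is invariant
to rescaling the distances; F is reported as infinite when SS_within
vanishes.

The dispersion-homogeneity test embeds the distances by principal
coordinates (double-centering), keeps negative-eigenvalue axes separately,
and computes each sample's distance to its group centroid as
sqrt(max(0, real² − imaginary²)); the one-way F on those distances is
tested by permuting the group labels over the fixed embedding.

When dispersions are heterogeneous, the distance entries are transformed
by rank-based inverse-normal scores, Φ⁻¹((rank − 0.5)/n) with average
ranks for ties (the rankit variant; Blom-type constants would change
nothing downstream since every consumer here is rank-based or permutation
-based), shifted to be non-negative so the matrix remains a
dissimilarity. The analysis order is: distances → dispersion test →
transform → PERMANOVA; running the PERMANOVA untransformed is a caller
choice, both orders being one function call apart. The cube-root
transform (d^(1/3)) is provided for rescaling distances ahead of
clustering displays.

UPGMA clustering delegates to average-linkage hierarchical clustering
(SciPy) and exports Newick with branch lengths derived from merge
heights/2, so leaf-to-ancestor path lengths are ultrametric. Richness
ANOVA is the standard one-way fixed-effects F test.

## Synthetic data generator

The generator produces the study conditions the analysis assumes: 3
habitats × 3 samples with one failed sample (8 analyzed), 2 PCR
replicates per sample, habitat taxon pools of 25 with 30% of each pool
shared across habitats (~60 taxa in play), log-normal abundances
(σ = 1.5) with the dominant shared taxon rescaled to hold 37% of the
reads of the pools containing it, per-taxon per-replicate detection
probability 0.85, host reads at 20% of each replicate, and 40,000 reads
per replicate allocated multinomially (column sums are exact by
construction). Identity draws for hit tables come from per-relatedness
uniform ranges (own species 98.5–100%, congeners ≤ 95%, confamilials
≤ 89%, others ≤ 82%), so the default structure is separable and
assignment should recover truth exactly; overlapping ranges are opted
into per test. Dropout and host-fraction defaults are stated choices of
plausible magnitudes — no field estimates of these rates exist for this
kind of survey.

Hit tables are simulated directly as identity draws, not by sequence
evolution plus alignment: the assignment rules consume identities only,
and a sequence-level simulation would exercise an aligner, not this
package. What the generator does **not** emulate: chimeras, PCR
stochasticity beyond Bernoulli dropout, tag jumps, index hopping,
contamination, or taxonomically biased reference-database coverage.
Passing tests on synthetic data therefore demonstrate correctness of the
pipeline's rules and calibration of its tests under the stated model,
not robustness to those real-data pathologies.

## Calibration

`permanova_null_rejection_rate` estimates the type-I error on random
symmetric distance matrices with uniformly random balanced labels
(default 500 data sets, 99 permutations each — enough permutations to
resolve α = 0.05 while keeping the 500-fold loop cheap).
`permanova_power_planted_effect` estimates power of Raup–Crick + PERMANOVA
against the generator's default habitat structure (200 surveys, 999
permutations); with pool overlap set to 1.0 the planted effect vanishes
and the same estimate returns to ≈ α.

## Packaged study table

`load_table1()` ships the final taxon table of the emulated cow-dung
survey: 57 taxa with lineage, habitat presence flags and read totals
(652,490 reads in sum). The derived summaries — top-3 read share 66%,
dominant taxon 37% (nearest percent), 12 orders, 29 named families, 9
taxa unresolved to species — are computed from these per-taxon counts.

## Known limitations

- One-way designs only: no multi-factor PERMANOVA, strata, or
  abundance-based dissimilarities.
- The taxonomy is single-rooted and strictly rank-ordered; merging
  conflicting taxonomies from multiple reference databases is out of
  scope (a pre-merged taxonomy is assumed).
- Rank thresholds (98/91/83) are taken as given, not re-derived from
  reference-database structure.
- Detrended correspondence analysis is not implemented; ordination
  questions are answered here by PERMANOVA plus clustering.
- Plotting is intentionally absent; all outputs are tables and Newick
  trees that standard tools render.
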