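# Methods

## Scope and model of the data

`omiclink` operates on K preprocessed omics matrices X⁽ᵏ⁾ (features ×
samples) over a shared sample cohort, a sample table of phenotype
attributes, and a knowledge base of gene sets, identifier mappings and
molecular networks. The package deliberately performs no preprocessing:
values are displayed and tested as given, because normalization choices are
platform-specific and better made upstream. Missing cells (tokens "", "NA",
"NaN", case-insensitive) are carried as NaN throughout — never imputed,
never rendered as zero.

## Identifier anchoring and link inference

Six identifier vocabularies act as linkers: Entrez, gene symbol, Ensembl,
RefSeq, UniProt, miRBase. The knowledge base maps (vocabulary, identifier)
pairs onto Entrez-style anchor strings; an Entrez identifier anchors to
itself. The map is many-to-many and ambiguity is preserved: a symbol
mapping to two anchors links through both. The design bias is to over-show
rather than silently drop — a visualization that omits a plausible link is
worse than one that draws an extra line the user can dismiss.

Inference connects rows i of layer A and j of layer B whenever their anchor
sets intersect. Rows with missing or unmapped identifiers join no edges. An
uploaded network file *replaces* the inferred map for its layer pair rather
than merging with it; we read the upload as an explicit override of an
inference the user considers wrong, and removal restores the inferred map
bit-exactly (both maps are retained). The merge alternative would make the
displayed edge set depend on upload history, which is harder to reason
about.

Nested identifiers (phosphosites under a parent protein accession) are
detected by partitioning a layer's rows on a parent metadata column; rows
with a missing parent become singleton groups keyed by row index, so the
partition property holds unconditionally.

## Statistical tests

Phenotypes are auto-typed: 2 distinct values → binary; >2 distinct,
all-numeric with distinct-count ≤ max(5, 10% of n) → categorical (numeric
encodings of groups); other numeric → continuous; non-numeric → categorical.
The distinct-count rule is a heuristic and can be overridden per phenotype.

Per feature, with missing values dropped pairwise:

| phenotype   | parametric            | nonparametric        |
|-------------|-----------------------|----------------------|
| binary      | Welch two-sample *t*  | Mann–Whitney *U*     |
| categorical | one-way ANOVA         | Kruskal–Wallis       |
| continuous  | least-squares slope *t* | — (not defined)    |

Choices where the convention was open, and why:

* **Welch rather than pooled *t*** — unequal group variances are the rule in
  omics; Welch is never worse and the flag is switchable in principle.
* **Two-sided alternatives throughout** — filtering for display has no
  privileged direction.
* **Mann–Whitney:** exact null distribution for combined n ≤ 20 without
  ties; tie-corrected normal approximation (with continuity correction)
  otherwise. Exactness at small n matters because the miniature cohorts the
  package targets (8 vs 9 subjects) sit squarely in the exact regime.
* **Kruskal–Wallis:** exhaustive permutation enumeration of the rank
  statistic for total n ≤ 12 (all label assignments; ties handled by
  average ranks, the tie-corrected H being a monotone transform shared by
  all permutations), chi-square approximation above. The threshold of 12
  keeps the largest enumeration (four groups of three: 369 600 splits)
  inexpensive.
* **Degenerate features:** all-constant features get p = 1 and a
  `zero_variance` flag (NaN propagation would silently drop them);
  groups internally constant at distinct values get p = 0 and a
  `degenerate_separation` flag; features leaving any group with <2 values
  get `insufficient_data` (p = NaN) and are excluded from adjustment and
  filtering.

## Multiple testing

Benjamini–Hochberg step-up: q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j, capped at 1,
invariant under input permutation. The adjustment background is exactly the
molecule set the user has selected for display, per layer and per test
batch — not the full dataset. This is the semantics a display filter needs:
the hypotheses at stake are the ones on screen. The filter keeps rows with
p ≤ α_p and (when an FDR level is set) q ≤ α_FDR, with BH computed once
over the whole selected background; the sequential alternative (BH on
p-survivors only) would make q depend on α_p and is not used.

## Enrichment

For a gene set with K members in the background (N = all anchors present in
the selected layer), n DE anchors and k = |DE ∩ set|, the p-value is the
upper hypergeometric tail P(X ≥ k). Reports are sorted ascending in p,
BH-adjusted, and filterable by minimum set size and minimum DE overlap —
the filters run before adjustment so q-values refer to the sets actually
reported.

## Ordering

Distances are pairwise-complete: each row pair is compared over the
coordinates both observe; Euclidean distances are rescaled by √(p/m) (p
total, m shared coordinates, as R's `dist` does) so sparsity does not
shrink distances; pairs with <2 shared coordinates, or an undefined Pearson
correlation (zero variance on the shared support), receive the maximal
defined distance in the matrix. A row with no observed values is an error
naming the row. Linkage uses SciPy's agglomerative implementation
(deterministic for fixed input; ties broken by its documented
lowest-index convention), with optional optimal leaf ordering.

**Synchronized mode** clusters one anchor layer and transports its display
order: each linked target row takes the position of its *first-displayed*
linked anchor row (many-to-one targets stay contiguous in original relative
order); unlinked target rows are appended afterwards in original relative
order. The append-after rule is a choice — interleaving unlinked rows at
their original positions was the alternative — made so the linked block
reads as one synchronized unit. Synchronizing over an empty link map is an
error: the caller should use independent mode.

**Nested (two-level) mode** summarizes each parent's child rows per sample
(average by default; maximum/minimum/sum selectable), clusters the parent
profiles (level 1), then clusters each parent's children independently
(level 2). Singleton parents skip level 2, and all-singleton nesting
reduces *bit-for-bit* to plain clustering — an invariant the tests enforce
for every metric/linkage combination.

Non-clustering sorts: ascending p (untestable features last), group-block
sort (a feature in several selected groups joins its first-selected group's
block), and stable lexicographic sample ordering by up to five phenotypes.

## Rendering

Scene geometry is a pure function of the workspace. Each panel gets an
independent diverging blue–white–red scale, symmetric about zero at the
1st/99th percentile of its displayed values (robust to outliers; absolute
values are not comparable across platforms, so no global scale exists).
Missing cells render light gray and are never interpolated. Group tag
tracks sit to the right of each panel (configurable); connection lines join
linked row centers of adjacent panels only, colored from the network file's
color column or a neutral gray. SVG output uses fixed 2-decimal coordinate
formatting and stable element identifiers, so identical workspaces produce
byte-identical files; PDF export draws the same geometry through
matplotlib's vector backend at one point per SVG unit.

## Workspace

The workspace serializes to a single versioned JSON document (`.omnl`) with
all data embedded — layers, samples, knowledge base, selections, link maps
(inferred and uploaded kept separately), orderings, filters, view settings
and the provenance log. Floats round-trip losslessly (shortest-repr), keys
are sorted, and save → load → save is byte-identical. Loading re-validates
every invariant and refuses partial state, naming the offending field.
Format version 1.1; 1.0 files load with documented defaults for fields
added since (`view.tag_track_side = "right"`). Every mutating operation
appends `{op, params}` to the provenance log; replaying a log against the
raw input files reproduces the workspace byte-exactly.

## Synthetic data

The generator plants known structure so every stage is testable offline:

* independent Gaussian noise per feature (unit SD), with a Student-t (df 3)
  option for exercising the rank tests on heavy tails;
* planted effects as mean shifts in SD units on named rows/groups — the
  reference study uses 100 features, 20 true effects of 3 SD, two groups of
  10 samples;
* identifiers drawn from the bundled miniature knowledge base (~50 genes,
  10 gene sets, 4 networks, one deliberately ambiguous symbol) so link
  inference has real mapping structure to chew on;
* negatively correlated miRNA–target pairs via a shared latent factor with
  opposite loadings;
* three miniature studies: a 2-layer time course with one-to-one links
  (8 time points × 2 replicates), a proteome + nested phosphosite pair with
  a kinase–substrate network file (5 subtypes × 4 samples), and a
  miRNA + protein pair with disjoint vocabularies, an uploaded target map
  and an 8-vs-9 binary phenotype.

What the generator does *not* emulate: real inter-feature correlation
structure, platform-specific missingness mechanisms, heteroscedastic
mean–variance trends, or the scale of real studies. Passing tests therefore
demonstrate correctness of the machinery (tests, adjustment, ordering,
linking, serialization, rendering) under clean sampling assumptions — not
that any biological conclusion drawn from real data is right.

## Problem sizes and limitations

The test suite and the acceptance script run the oracle comparisons at the
sizes where exhaustive enumeration is exact (rank tests at group sizes ≤ 6,
hypergeometric tails at N ≤ 15), the FDR study at 500 replicates × 100
features, and the power study at 100 seeds — sizes chosen so the whole
suite completes in about a minute on one CPU while keeping Monte-Carlo
error well below the margins being checked. Known limitations: no
moderated/empirical-Bayes tests or covariate adjustment; no miRNA-target or
kinase-substrate *prediction* (relationships always come from the KB or an
upload); no interactive client; the `.omnl` format is this package's own,
not compatible with any other tool's workspace files.
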