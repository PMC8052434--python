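# omiclink

**Linked multi-omics heatmaps, headless.** `omiclink` ingests preprocessed
omics tables (transcriptome, proteome, phosphoproteome, miRNA, metabolome,
...), connects their features across layers through standard-identifier
linkers or user-supplied networks, selects features by keyword search or
gene-set enrichment, filters them by differential expression with
Benjamini–Hochberg FDR control, orders them by synchronized, independent, or
two-level nested hierarchical clustering, and renders the result as
connected heatmap panels in SVG or PDF — all reproducibly, from a
serializable workspace file.

## Who it is for

Computational biologists who have several preprocessed omics matrices over
the same samples and want to *look at the actual quantitative data* for a
biologically coherent slice of it — a pathway, a GO term, a kinase and its
substrates — with the cross-layer relationships drawn explicitly, rather
than a low-dimensional abstraction. The package does **no** normalization,
imputation or batch correction; it expects display-ready values.

## The core machinery

* **Linkers.** Each layer's identifier columns can be tagged with one of six
  standard vocabularies (Entrez, gene symbol, Ensembl, RefSeq, UniProt,
  miRBase). Every identifier is mapped to an Entrez anchor via the knowledge
  base; rows in two layers sharing ≥1 anchor are connected. Ambiguous
  identifiers connect through *all* their anchors. Layers without shared
  anchors stay independent unless a 2–4-column network file
  (`id_a, id_b[, color[, descriptor]]`) is uploaded, which overrides
  inference for that pair (removal restores the inferred map exactly).

* **Differential-expression filtering.** Phenotypes are auto-typed as
  binary / categorical / continuous. Tests: Welch *t* or Mann–Whitney *U*
  (binary), one-way ANOVA or Kruskal–Wallis (categorical), least-squares
  slope *t* (continuous). Rank tests use exact small-sample null
  distributions (MWU: combined n ≤ 20 tie-free; KW: exhaustive enumeration
  for n ≤ 12). BH adjusted p-values are computed over exactly the molecules
  currently selected — the display background, not the whole dataset:
  q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ m·p₍ⱼ₎/j, capped at 1.

* **Enrichment.** Upper-tail hypergeometric test per gene set,
  P(X ≥ k) with k = |DE ∩ set ∩ background|, K = |set ∩ background|,
  n = |DE|, N = |background|, reported ascending in p with BH q-values.

* **Ordering.** Agglomerative clustering (Euclidean or 1 − Pearson;
  average/complete/single/ward linkage; optional optimal leaf ordering)
  with pairwise-complete distances. *Synchronized* mode transports the
  anchor layer's display order through the link map; *nested* mode clusters
  parents (e.g. proteins) on a summary of their children (e.g. phosphosite
  average) and then the children within each parent.

* **Rendering.** One panel per layer with its own diverging color scale
  (symmetric about 0 at the 1st/99th percentile), functional-group tag
  tracks, phenotype header tracks, and straight connection lines joining
  linked feature rows of adjacent panels. Identical workspaces export
  byte-identical SVG.

## Worked example

The bundled miniature time-course study (two layers, 12 genes, 8 time
points × 2 replicates, ER-stress-style trend planted in 6 genes) runs
through the whole workflow from a shell:

```sh
omiclink make-fixtures --out fx --which cs1
omiclink init -w ws.omnl \
    --layer 'mrna=fx/cs1/mrna.tsv;meta=gene_symbol;tag=gene_symbol:GeneSymbol' \
    --layer 'protein=fx/cs1/protein.tsv;meta=gene_symbol;tag=gene_symbol:GeneSymbol' \
    --samples fx/cs1/samples.tsv --kb fx/cs1/kb
omiclink search -w ws.omnl "unfolded protein response"
# GO      GO:0030968      endoplasmic reticulum unfolded protein response
omiclink select -w ws.omnl GO:0030968
# {"mrna": 10, "protein": 10}
omiclink filter -w ws.omnl --phenotype time --test parametric --p 0.05 --fdr 0.05
# {"retained": {"mrna": 6, "protein": 6}}
omiclink cluster -w ws.omnl --mode synchronized --anchor mrna
omiclink render -w ws.omnl upr.svg
omiclink save -w ws.omnl shared.omnl
```

The `select` line prints how many features each layer contributes for the
chosen GO term (10 of the 12 genes belong to it). The `filter` line keeps
the 6 genes per layer whose expression tracks time at p ≤ 0.05 and BH-FDR
≤ 5% — exactly the 6 with the planted trend. `upr.svg` contains the two
synchronized heatmaps with 6 one-to-one connection lines; `shared.omnl` is
a self-contained JSON workspace that reloads bit-exactly anywhere
(`omiclink open -w shared.omnl`), and its embedded provenance log replays
to the identical state.

The same API is available from Python (`omiclink.Workspace`,
`infer_links`, `de_test`, `bh_adjust`, `hcluster`, `build_scene`, ...).

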