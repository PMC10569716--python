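# nesskit

Statistical toolkit for regional composition and cis-regulatory analysis
of multi-region single-cell multi-omic (snRNA-seq + snATAC-seq) atlases,
such as brain-wide surveys where dozens of dissected regions are
profiled from the same individuals.

Whole-organ atlases face a recurring set of questions that sit between
standard clustering and bespoke statistics: Which cell subtypes are
regionally specific, and which genes track a region even when clusters
do not? Which reverse-transcription barcodes carry cross-well
contamination? Which accessible-chromatin peaks regulate which nearby
genes, and in which direction? `nesskit` packages the machinery for
these questions:

* **lochNESS** — a per-cell regional neighborhood-enrichment score. For
  cell *n* and region *m* within a cell type of *N* cells,

  ```
  lochNESS(n, m) = (k_m(n) / k) / (N_m / N)
  ```

  the fraction of region-*m* cells among the *k* nearest transcriptional
  neighbors of *n*, relative to the region's overall share. 1 = no
  enrichment. A normalized variant makes rows comparable across a
  region subset, and a per-gene negative-binomial GLM
  (`log E[y] = β0 + Σ βm·lochNESS_m + offset`) finds region-biased
  genes with BH-adjusted Wald tests.
* **Regional specificity and composition ratios** — base-2
  Jensen-Shannon divergence between a cell type's regional distribution
  and the global one (range [0, 1]), and capped log2 ratios of
  within-region subtype composition against the cross-region average.
* **QC screens** — the nucleus filters (RNA: UMI ≥ 100, genes < 2500,
  mito < 5%; ATAC: 1000 ≤ UMI < 100,000, FRiP ≥ 30%), per-cell
  (score > 0.20) and per-cluster (mean score > 0.15) doublet rules, and
  a barcode-contamination screen that flags RT barcodes with > 10,000
  cells whose class/subtype composition diverges from their sample
  (class JSD > 0.15 and subtype JSD > 0.075).
* **Metacell peak–gene linking** — k-means metacells on a joint
  embedding (k = floor(n_cells/250) by default), pseudobulk log2CPM,
  logistic regression of per-cell binary peak accessibility on metacell
  expression for every peak within 150 kb of the promoter (strand-aware
  TSS − 2 kb), combination with an external evidence stream (both
  BH-adjusted p < 0.05), direction from the coefficient sign, and
  one-vs-rest differential-accessibility marker peaks.
* **TF activity sign** — Pearson correlation of motif accessibility vs
  TF expression across cell-group summaries: activator (r > 0) or
  repressor (r < 0).
* **Synthetic data** — negative-binomial multi-region RNA counts with
  planted region-biased genes, mixture doublets, barcode contamination,
  a directly generated embedding, and logistic peak–gene links, all
  deterministic given a seed. Every downstream claim in the test suite
  is verified against this planted truth.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Plant a +1.5 log2 expression effect for one gene in region A, score the
cells, and recover the gene:

```python
import nesskit as nk

cfg = nk.SimConfig(
    n_cells=3000, cell_types=["T1"],
    type_profiles={"T1": [1.0] * 200},
    region_bias=[("gene_0100", "A", 1.5)],
    seed=1,
)
rna, meta, emb, truth = nk.simulate_rna(cfg)

L = nk.compute_lochness(emb, meta["region"], k=25)
print("mean lochNESS(A) in region A cells:",
      round(L.raw[(meta.region == "A").to_numpy(), L.regions.index("A")].mean(), 2))

table = nk.lochness_glm(rna, L)
hit = table[(table.gene_id == "gene_0100") & (table.region == "A")].iloc[0]
print(f"gene_0100 ~ region A: beta={hit.beta:.2f}, BH-adjusted p={hit.p_adj:.2e}")
print("metacells for a 2,583,967-cell atlas:", nk.choose_n_meta(2_583_967, 250))
```

prints

```
mean lochNESS(A) in region A cells: 2.95
gene_0100 ~ region A: beta=0.29, BH-adjusted p=2.14e-08
metacells for a 2,583,967-cell atlas: 10335
```

Region-A cells sit in transcriptional neighborhoods almost 3× enriched
for region A (no enrichment = 1), the planted gene is recovered with a
positive coefficient at genome-wide significance, and the metacell rule
reproduces the full-atlas arithmetic. Regional specificity works off
composition tables:

```python
comp = nk.regional.composition_table(meta, "cell_class", "region")
nk.regional_specificity(comp)
```

For a three-type dataset where T1 concentrates in one of four regions
(70/10/10/10), T2 is uniform, and T3 splits between two regions, the
scores come out 0.104, 0.014 and 0.082 — uniform types score near 0,
concentrated ones higher, on the [0, 1] JSD scale.

A `nesskit` command-line interface mirrors the library
(`simulate`, `qc`, `lochness`, `specificity`, `links`, `tfcorr`), each
subcommand reading a YAML config and writing TSV outputs plus a log with
the config hash and seed.

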