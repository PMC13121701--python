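# medivar

**Does the culture medium or the donor's genetic background dominate a
primary-cell transcriptome?**

Primary cells — such as human umbilical vein endothelial cells (HUVECs)
isolated from individual donors — are cultured in media whose composition
varies widely between laboratories. Both the medium and the donor's genetic
background shape the cells' expression profile, and disentangling the two is
essential for designing reproducible in-vitro experiments. `medivar`
implements a complete variance-attribution workflow for the canonical
crossed design (a handful of donor lines × a handful of media, one array
per cell), built around gene-level microarray intensity matrices:

- **Pre-processing** — per-sample scaling to a housekeeping-gene reference,
  a detection limit set at the 95th percentile of pooled negative-control
  (lineage-marker) intensities, a three-criterion expressed-gene filter,
  and exclusion of Y-chromosome genes and *XIST* so donor sex cannot
  masquerade as a genetic-background effect.
- **Differential expression** — every pair of media and every pair of donor
  lines compared by *replicate swapping*: the other factor's levels serve as
  replicates. Per gene, log2 fold change and a moderated t-statistic with
  empirical-Bayes variance shrinkage
  `s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` (hyperparameters moment-matched on
  the spread of log s²_g; `d₀ = 0` recovers the plain pooled t), BH-adjusted
  p-values, four-way volcano classes, DE-set collection with per-comparison
  summaries, top fold-change subsets and top-gene tables.
- **Structure** — per-gene z-scores of log2 intensities, hierarchical
  clustering of samples (Euclidean distance, complete linkage), Spearman
  correlation on raw values, PCA with per-component variance explained and
  gene importances, and a *purity* statistic: cut the dendrogram into k
  clusters and score the fraction of samples whose cluster's majority label
  matches their own.
- **Gene sets** — GMT ingestion, GO-style annotation filtering to
  experimentally supported protein-coding genes, a hypergeometric
  over-representation test, and a nine-category endothelial-function
  roll-up (cell cycle, angiogenesis, adhesion, inflammation, EMT,
  programmed cell death, hemostasis, vascular permeability, blood
  pressure).
- **Preranked GSEA** — genes ranked by medium-mean / overall-mean
  expression ratio; a weighted Kolmogorov–Smirnov running sum gives the
  enrichment score ES, gene-label permutations give NES and an add-one
  nominal p, and a run-wide Benjamini–Hochberg threshold flags FDR-level
  findings.
- **Synthetic data** — a seeded generator emulating the 3-donor × 4-medium,
  12-sample design: log-normal baselines, additive per-gene medium and
  donor effects on the log2 scale, housekeeping and floor-level
  negative-control probes, sex-linked genes, and optional spike-ins — with
  full ground truth, so every stage is testable without external data.

## Worked example

```python
import numpy as np
import medivar as mv

matrix, samples, genes, truth = mv.generate(mv.SimConfig(seed=42, n_genes=5000))
retained, report = mv.run_preprocess(matrix, genes)
print(f"retained {report.n_retained} of {report.n_input} genes; "
      f"detection limit {report.detection_limit_normalized:.2f}")

res = mv.fit_contrast(np.log2(retained), samples,
                      mv.ContrastSpec("medium", "EBM", "MCDB-S"))
print(res.summary())

dend = mv.cluster_samples(mv.zscore_log(retained))
print("purity by medium:", mv.grouping_purity(dend, samples["medium"], 4))
print("purity by donor: ", mv.grouping_purity(dend, samples["donor"], 3))
```

prints

```
retained 4931 of 5000 genes; detection limit 11.67
Contrast EBM_vs_MCDB-S (medium; n=3 vs n=3)
  moderation prior: d0=14.02, s0^2=0.1334
  thresholds: FC >= 2.0, BH-adjusted p < 0.05
  volcano classes: red=244, green=56, blue=28, grey=4603
  top genes by |log2FC|:
    g01232: FC=3.59 (down), adj p=0.0077
    g03222: FC=3.56 (down), adj p=0.0077
    g04266: FC=3.49 (down), adj p=0.0106
purity by medium: 1.0
purity by donor:  0.3333333333333333
```

Reading the output: 69 low-intensity genes fall below the detection limit
and 11 sex-linked genes are excluded; between the EBM and MCDB-S media, 244
genes change at least two-fold with BH-adjusted p < 0.05 ("red" volcano
class); and the genome-wide dendrogram cut into four clusters groups the 12
samples perfectly by medium (purity 1.0) while a three-cluster cut does not
recover donors — under these simulation conditions the medium dominates, as
it does in real endothelial-cell data.

The same workflow runs from the shell:

```bash
medivar simulate --seed 42 --n-genes 5000 --out run/
medivar preprocess --matrix run/matrix.tsv --genes run/genes.tsv --out run/
medivar de --matrix run/matrix_preprocessed.tsv --samples run/samples.tsv --out run/
medivar structure --matrix run/matrix_preprocessed.tsv --samples run/samples.tsv --out run/
medivar all --seed 42 --out run/     # or everything at once, YAML-configurable
```

Real data drop in the same way: a genes × samples TSV intensity matrix, a
sample table (donor, medium, sex) and a gene table (symbol, chromosome,
housekeeping/negative-control flags), e.g. exported from an ArrayExpress
deposition such as E-MTAB-15672.

## Documentation

`docs/methods.md` describes the statistical model, the synthetic-data
generator and its limits, numerical conventions, and known limitations.
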