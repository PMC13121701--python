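# Methods

## The design and the replicate-swapping trick

The workflow targets a fully crossed two-factor design with a single
observation per cell: D donor lines × M media, one expression profile per
(donor, medium) pair (the canonical case is 3 × 4 = 12 arrays). Neither
factor has conventional replicates, so pairwise comparisons borrow the
other factor as replication: comparing two media treats the D donors
cultured in each medium as replicates; comparing two donors treats the M
media as replicates. Each contrast is therefore an ordinary two-group
comparison, at the price of absorbing the other factor's effects into the
residual. This inflates the gene-wise variance for genes strongly driven by
the nuisance factor and is the main reason the moderated t (below) rather
than a per-gene t is used. A two-way additive model would use the data more
efficiently; replicate swapping is kept because it is the estimand the
pipeline is designed to reproduce and it keeps every contrast interpretable
as "difference of condition means".

## Pre-processing

1. **Housekeeping selection.** From a candidate list (default: the
   annotation's `hkg_candidate` flags), the k = 12 genes with the smallest
   sample standard deviation of log2 intensity across samples are taken as
   the reference. SD is computed on the log scale because every downstream
   analysis is log-scale and because log-SD ranking is invariant to overall
   probe brightness; ties break lexicographically by gene id.
2. **Normalization.** Each sample is scaled multiplicatively so its mean
   housekeeping intensity equals the grand mean of per-sample housekeeping
   means. Multiplicative raw-scale scaling (additive on the log scale) is
   the standard reference-gene convention, preserves non-negativity, and is
   idempotent.
3. **Detection limit.** All intensities of the negative-control genes
   (lineage markers not expected in the assayed cell type) are pooled
   across samples; the limit is the 95th percentile of that pooled vector,
   by linear interpolation between closest ranks (position 1 + (n−1)q).
   The limit used for filtering is computed on *normalized* values; the
   raw-scale value is also recorded so either convention can be checked
   against an external dataset.
4. **Expressed-gene filter.** A gene is kept iff it is strictly above the
   limit in ≥ 4 samples, or above twice the limit in ≥ 2 samples, or above
   three times the limit in ≥ 1 sample. "Above" is strict; boundary
   equality fails. The rule is monotone in the limit.
5. **Sex-gene exclusion.** Genes on chromosome Y and the gene with symbol
   *XIST* are removed, because with donors of mixed sex they are
   deterministic donor markers and would contaminate genetic-background
   contrasts. A flag re-includes them for the quality-control contrast
   (male-vs-female comparisons should, and do, flag exactly these genes).
   Genes missing annotation are retained, never silently dropped.

Counts telescope across stages and are recorded in the `PreprocessReport`.

## Moderated differential expression

For contrast A vs B with n_A and n_B replicate samples, per gene g:

- log2FC_g = mean(log2 A) − mean(log2 B);
- pooled variance s²_g on d_g = n_A + n_B − 2 df;
- shrunk variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g);
- t_g = log2FC_g / (s̃_g √(1/n_A + 1/n_B)), referred to t with d₀ + d_g df;
- BH step-up adjustment across all genes in the contrast.

The prior (d₀, s₀²) is estimated by moment matching on log s²_g: under a
scaled-F model, e_g = log s²_g − ψ(d_g/2) + log(d_g/2) has excess variance
ψ′(d₀/2) beyond the sampling term ψ′(d_g/2), and d₀ follows by trigamma
inversion (Newton iteration). If the observed spread does not exceed the
sampling term, d₀ = ∞ and s₀² is the mean gene variance (complete pooling,
normal reference distribution). Zero-variance genes carry no information on
the log scale and are excluded from estimation; an all-zero-variance matrix
is a degenerate-fit error. `d₀ = 0` is exposed as a switch and reduces
exactly to the textbook pooled t — useful for diagnosing discrepancies
against other implementations. The estimator and shrinkage agree with the
R reference implementation (limma) to ~1e-6 relative on shared fixtures;
that cross-check lives in the test suite, not in the implementation path.

Conventions: t = 0 (hence p = 1) when log2FC = 0 even if the variance is
also 0; volcano classes use |log2FC| ≥ log2(threshold) and adjusted
p < α strictly, with boundary p = α non-significant (red = both, green =
fold change only, blue = significance only, grey = neither). DE sets are
unions of red genes over a factor's contrasts; per-comparison summaries are
the mean and n−1 SD of red counts; the top-f subset takes, per contrast,
the ⌈f·n_red⌉ red genes of largest |log2FC| and unions them across the
factor's contrasts (this per-contrast-then-union reading, not f of the
pooled union, is what reproduces the published subset sizes for this kind
of design).

## Structure analyses

- **Z-scores**: per-gene standardization of log2 intensities (n−1 SD);
  constant rows map to zero with a warning. Log base cancels in z-scores.
- **Clustering**: complete-linkage agglomeration on Euclidean distances
  between sample columns (scipy linkage; deterministic tie handling with
  the fixed column order). Dendrograms export to Newick.
- **Purity**: cut into k clusters (removing the k−1 tallest merges) and
  score Σ majority-label counts / n. Purity 1.0 at k = M by medium and
  < 1.0 at k = D by donor is the quantitative form of "samples cluster by
  medium, not donor".
- **Spearman correlation** between samples on raw intensities (mid-ranks
  for ties); constant columns yield undefined entries and are an error
  unless explicitly allowed. Positive semi-definiteness is not asserted —
  it is not guaranteed for Spearman matrices.
- **PCA** by SVD of the column-centered samples × genes matrix of z-scores;
  R² per component is the percentage of total variance, gene importance is
  |loading|, and each component's dominant loading is made positive for a
  reproducible sign. Requested components beyond the data rank are reduced
  with a warning (a 12-sample design has rank ≤ 11).

## Over-representation and GSEA

ORA uses the upper-tail hypergeometric p = P(X ≥ overlap) with the
background defaulting to the post-filter transcriptome, BH across sets.
The g:SCS correction of web enrichment tools is deliberately not
reproduced; published term counts from such tools are therefore not
comparable quantities. Annotation filtering keeps records with
experimental evidence codes (EXP, IDA, IPI, IMP, IGI, IEP), matching
taxon, and protein-coding type; GO accessions tolerate comma-grouped
digits and are zero-padded on input.

Preranked GSEA ranks genes by mean(intensity in medium)/mean(intensity
overall) on the raw scale — the ratio is monotone-equivalent to its log for
ranking, and raw-scale averages are the documented convention for this
metric. The running sum steps up by |metric|^w (w = 1 default, normalized
over the set's hits) at member genes and down by 1/(N − N_hit) otherwise;
ES is the maximum signed deviation, with ties resolved positive. At w = 0
the ES is exactly the signed KS statistic between hit and miss positions.
Nulls are gene-label permutations (phenotype permutation is impossible with
one array per cell): m positions are drawn uniformly without replacement
per permutation. NES divides ES by the mean |null ES| of matching sign;
the nominal p is the add-one estimator over matching-sign nulls (never
exactly 0, bounded below by 1/(nperm+1)); fewer than 10 matching-sign
nulls flags the result unstable. The BH threshold — the largest sorted
p_(i) ≤ iα/m — is computed across all set × medium tests of a run and
sets the FDR flag. Permutation ES values are computed vectorized from
sorted hit positions (the walk's extremes occur only adjacent to hits),
which is algebraically identical to the full walk and is what makes
1000-permutation runs cheap.

## The synthetic-data generator

`SimConfig`/`generate` emulate the 12-sample study design: log2 intensity
of an ordinary gene is baseline + medium effect + donor effect + noise,
exponentiated and clipped below at 1.0 (scanners report positive
fluorescence). Effects are drawn per gene per level from centered normals
and re-centered across levels, so "fold change vs the overall average" is
well defined and pairwise level differences are preserved. Defaults, all
log2-scale SDs:

| parameter | default | rationale |
|---|---|---|
| `baseline_mean`, `baseline_sd` | 8, 2 | raw intensities ~2⁸, two orders of magnitude spread |
| `sigma_medium` | 0.35 | few-percent of genes beyond two-fold per media contrast, the scale seen in primary-cell media comparisons |
| `sigma_donor` | 0.30 | slightly weaker than medium — the regime the pipeline quantifies |
| `sigma_noise` | 0.25 | ≈18% technical CV, typical validated array reproducibility |
| `frac_affected_*` | 1.0 | every gene draws both effects; per-gene z-scoring equalizes scale, so factor dominance is a property of the spread ratio, not of a minority of genes |
| `floor_level` | 10 | negative-control floor, an order of magnitude below typical baselines |
| `n_hkg`, `n_negative`, `n_y_genes` | 14, 12, 10 | control-panel sizes of the emulated platform |

Housekeeping genes receive no condition effects; negative controls sit at
`floor_level` with 0.1 log2-SD multiplicative jitter (so percentile
computation is non-degenerate); Y-linked genes are floored in female-donor
samples and *XIST* in male-donor samples. Spike-ins (`n_spiked`,
`spike_log2fc`, `spike_medium`) add a fixed effect in exactly one medium
for recovery testing. A replicate count is accepted for test flexibility
(default 1, mirroring the study design). Same config ⇒ bit-identical
output.

What the generator does **not** emulate: probe-level replication and
summarization, dye/batch effects, intensity-dependent variance, correlated
gene modules, and a realistic unexpressed-gene fraction (simulated
baselines put almost all genes above the detection floor, unlike real
arrays where a third of genes may fail the filter). Passing tests
demonstrate the pipeline's statistical correctness and calibration under
the stated model — not robustness to artifacts the generator omits.

## Numerical and degenerate-input conventions

- Percentiles: linear interpolation between closest ranks throughout.
- All SDs use the n−1 denominator.
- Strict inequalities at every significance and detection boundary.
- Floats serialize at 17 significant digits and parse with round-trip
  precision, so pipeline outputs are byte-stable across reruns.
- Ties: gene-id order breaks ranking ties (rank metric, housekeeping SD,
  top-gene tables after adjusted-p); the ES sign convention resolves exact
  positive/negative ties to positive.
- Problem sizes in the shipped verification runs (array-scale 20,672-gene
  main run; 10,000-gene null calibration; 2,000-gene recovery and purity
  studies; 1,000 permutations) were chosen as the smallest sizes at which
  the measured quantities are stable to well within their assertion
  margins.

## Known limitations

- Replicate swapping confounds the nuisance factor into the residual;
  effect estimates for one factor are conservative when the other factor
  is strong.
- Gene-label permutation GSEA ignores inter-gene correlation, so nominal
  p-values are exact only under the independence null; this matches the
  preranked convention but understates FDR for tightly co-regulated sets.
- The moderation hyperparameter estimator assumes an inverse-chi-square
  variance prior without an intensity trend; no variance–intensity
  moderation is provided.
- The correlation heatmap's sample ordering uses Euclidean distance
  between correlation rows (not 1 − r); both are defensible and the choice
  is documented here because displays differ between them.
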