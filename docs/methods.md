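# Methods

## Problem and model

Tumor tissue profiled by droplet scRNA-seq mixes malignant cells with
microenvironment populations — in glioblastoma: endothelial cells (ECs),
mural cells (pericytes / vascular smooth muscle), T cells,
tumor-associated microglia/macrophages (TAMs) and oligodendrocytes
(OLGs).  Whether a population shares lineage with the tumor can be asked
through copy-number variations (CNVs): cells descended from the same
malignant ancestor carry the same chromosome-scale dosage changes, and a
gene's expression scales, on average, with the copy number of its locus
(the dosage effect).  `sccnvlineage` infers per-cell CNV profiles from
expression alone, groups candidate tumor cells into clones, and asks for
every cell whether its CNV evidence places it with a malignant clone or
with the diploid microenvironment.

### CNV inference

For cell c and gene g with raw UMI count x_gc and cell library size
N_c, the chain is:

1. **QC.**  Cells with a mitochondrial count fraction above
   `max_mito_frac` (default 0.05) or a hemoglobin (red-blood-cell)
   fraction at or above `max_rbc_frac` (default 0.05) are removed.
2. **Normalization.**  y_gc = log2(1 + x_gc · S / N_c) with scale
   S = 10,000.  Base 2 makes one unit of the CNV stream read as a
   two-fold dosage change.
3. **Reference centering.**  A configured set of reference cell types
   assumed karyotypically normal (T cells for the mouse-style setting;
   T + TAM + OLG for the human-style setting) defines the diploid
   baseline: their per-gene mean is subtracted from every cell.  At
   least `min_reference_cells` (default 20) reference cells are
   required.  Centered values are clipped to ±`cap` (default 3.0) to
   bound the leverage of outlier genes before smoothing.
4. **Smoothing.**  Genes are sorted by (chromosome, start position,
   gene id) and each cell's centered values are averaged over a moving
   window of `window_genes` genes (default 101 — the odd, symmetric
   counterpart of a 100-gene window).  Windows shrink at chromosome
   edges and never cross a chromosome boundary; chromosomes shorter
   than the window are averaged over their full span.  No padding is
   ever invented.
5. **Per-cell recentering** (default on).  Each cell's median smoothed
   value is subtracted, removing residual per-cell technical offsets so
   that diploid cells center at 0.

The result is the CNV matrix: 0 ≈ diploid, positive gain-like,
negative loss-like.

### Clonal grouping and the two CNA-based measures

Cells not confidently annotated as a stromal type (see below) form the
candidate pool.  Agglomerative clustering (Euclidean distance, Ward
linkage) of candidate CNV profiles is cut into a user-chosen k groups
(k = 3 for the mouse-style setting, 2 for the human-style setting);
groups are labeled A, B, … in decreasing size with a lexicographic
tie-break on the smallest member id, and groups below `min_group_size`
(default 20) cells are discarded as noise.  Each group's **signature
chromosomes** are those whose mean CNV value over the group exceeds
`min_effect` (default 0.05) in absolute value, falling back to the
single largest-effect chromosome, and overridable by an explicit
per-group list so published per-sample chromosome selections can be
reproduced verbatim.

Per cell, two statistics are computed:

* **CNV signal** = mean of squared CNV values over a chromosome set —
  genome-wide for reporting, and over a group's signature for the
  designation rule (both definitions are in circulation; the package
  computes both).
* **CNV correlation** = Pearson correlation between the cell's CNV
  profile restricted to a group's signature chromosomes and the group's
  mean profile on those genes.  A zero-variance vector makes the
  correlation undefined; it is then flagged and treated as 0 rather
  than propagating NaN, because a constant profile carries no evidence
  of clonal kinship.

### Designation rule

A cell's best group is the one with maximal correlation.  The cell is
designated **malignant** iff its signature CNV signal exceeds the
`signal_quantile` (default 0.95) of the reference cells' signals *and*
its best correlation exceeds the `correlation_quantile` (default 0.95)
of the reference cells' best correlations.  Quantile calibration makes
the rule self-contained and scale-free: no absolute cutoff has to be
chosen, and by construction about 5% of diploid cells land above each
reference quantile, so the AND of the two measures keeps the null
false-positive rate at a few percent.  Cells with only undefined
correlations are non-malignant.  How to combine per-group evidence into
one call is not uniquely determined by the source analyses; the
best-group rule is this package's construction.

### Marker-based annotation

Stromal types are labeled from small lineage-marker panels (EC:
Pecam1/Tek/Cldn5; mural: Kcnj8/Pdgfrb/Acta2/Tbx18; T: Cd2/Cd3d/Cd3e/
Cd3g; TAM: Cd14/Tmem119/Aif1; OLG: Cldn11/Mag/Mbp/Klk6; human panels
use upper-case symbols).  A cell's score for a type is the mean
log-normalized expression of the panel genes present; the top type is
assigned when the score is ≥ `min_score` (default 0.25) and beats the
runner-up by ≥ `margin` (default 0.1).  All other cells remain
"malignant-candidate" and enter the clustering pool.  This transparent
mean-of-panel score is adequate for well-separated panels; for shallow
real data a rank-based module score would be more robust, and external
labels from any prior clustering can be supplied to bypass the module
entirely.  Note that the score scale depends on sequencing depth
through the log-normalization, so `min_score` is calibrated for
libraries of roughly 10⁴ UMIs; very shallow libraries inflate
per-count scores.

## Synthetic data generator

The simulator emulates the study conditions at desk scale.  Counts are
negative binomial with mean

    mu_gc = baseline_g · dosage_{clone(c), chrom(g)} · lib_c · marker_tg

and variance mu + α·mu² (dispersion α = 0.3), followed by independent
extra zero-inflation ("dropout", default 0.05).  Components:

* `baseline_g` — log-normal(0, 1) per gene (median library ≈ 20,000
  UMIs over 12,000 genes, ≈ 6,000 genes detected per cell, a deeply
  sequenced 10x-style regime);
* `dosage` — whole-chromosome multipliers per clone: 1.5 = single-copy
  gain, 0.5 = single-copy loss (sub-chromosomal events are out of the
  default model: the analysis operates at chromosome granularity);
* `lib_c` — log-normal library-size factor (σ = 0.3), normalized to
  mean 1;
* `marker_tg` — marker genes are expressed at `marker_fold` (8×)
  baseline in their own cell type and suppressed to
  `marker_offtarget_factor` (1/64) of baseline everywhere else.  The
  suppression term reflects the lineage specificity of real marker
  genes (Cd3e is essentially silent outside T cells); without it,
  baseline-level marker expression in tumor cells would make panel
  scores meaningless for screening.

The frozen default configuration is 12,000 genes on 20 chromosomes
(600 each); clones A/B/C with 300/300/200 cells, each carrying 4–8
events drawn without replacement per clone at dosage 0.5 or 1.5; and
300 T / 200 TAM / 150 OLG / 90 EC / 80 mural diploid cells — 1,620
cells total, a deliberate ~7× downscale of a typical 10⁴-cell tumor
sample that preserves the population structure.  A clone-free variant
(1,000 cells, same stromal proportions) serves as the null for
calibration checks.  All draws flow from a single integer seed; a fixed
seed gives bit-identical matrices.

What the generator does **not** emulate: doublets, batch effects,
ambient RNA, gene-length/GC biases, sub-clonal breakpoints,
transcriptional covariance between neighboring genes, and the
aberrant marker expression by tumor cells seen in real glioblastoma.
Passing recovery tests therefore demonstrates correctness of the
machinery under the stated generative model, not performance on real
tissue.

## Numerical choices

* Smoothing uses per-chromosome cumulative sums (O(genes·cells)); a
  width-1 window returns the input unchanged.  Equivalence with a
  brute-force per-gene window mean is asserted to ~1e-12 on randomized
  instances.
* Order invariance is exact, not approximate: reference means, group
  mean profiles and quantiles accumulate over cells sorted by cell id,
  and genes are sorted before smoothing, so permuting input rows or
  columns reproduces results bitwise.
* Ties in the best-group argmax resolve to the earlier (larger) group;
  identical candidate profiles produce a deterministic, documented
  dendrogram cut rather than an error.
* Undefined correlations are flagged, never silent NaN.
* Matrix Market I/O delegates to scipy; triplet indices are 1-based.
* Gene coordinates are opaque sort keys; chromosome order is the order
  of first appearance in the annotation unless configured.

## Known limitations

* Expression-based CNV inference cannot see copy-neutral events and is
  confounded by strong transcriptional programs; chromosome-scale
  granularity hides focal amplifications.
* k (the number of clones) is user-supplied; no model selection is
  attempted.
* Per-cell annotation may differ from cluster-level annotation at
  cluster boundaries; external labels can be supplied where a prior
  clustering exists.
* The designation thresholds are quantiles of the reference
  distribution, so contamination of the reference pool (e.g. tumor
  cells mislabeled as T cells) inflates the cutoffs; the margin rule in
  annotation keeps this rare on simulated data but it should be audited
  on real data.
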