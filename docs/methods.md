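# Methods

## Problem

Single-cell bisulfite technologies (snmC-seq and relatives) observe only a
few percent of the ~26 million CpG dinucleotides in each cell, with one or
two reads per covered site. `scmeth` predicts, for every CpG site and every
cell, the probability that the site is methylated, given (a) the reference
DNA sequence around the site and (b) the methylation levels of neighboring
CpGs aggregated within pre-defined cell clusters.

## Binary methylation states

Per-cell cytosine calls arrive as ALLC-style records (chrom, 1-based
position, strand, context, methylated reads `mc`, total reads `cov`). A
CpG site in a cell is assigned state 1 when all mapped reads support
methylation (`mc == cov`), state 0 when none do (`mc == 0`); sites whose
reads disagree are excluded from both training and evaluation — they carry
no binary label rather than a missing one. At single-cell read depths
(mostly 1–2 reads) this discards few sites while keeping labels unambiguous.

## Pre-defined cell clusters and cluster profiles

Cells are partitioned before imputation using methylation levels in
non-overlapping genomic bins (100 kb for mammalian genomes; 20 kb for the
1 Mb synthetic genomes so that a comparable number of CpGs falls in each
bin): per (cell, bin), level = Σmc/Σcov; missing bins are mean-imputed per
bin for clustering only; PCA (20 components) followed by k-means with a
fixed seed. Externally supplied labels (e.g. published cell-type
assignments) are accepted everywhere a partition is needed and bypass
clustering. The per-cluster methylation level of a site is read-weighted:
summed methylated reads over summed total reads across member cells.

## Model

Each target CpG yields one example with two modalities.

**DNA module.** An L×4 one-hot window (L = 2000 full scale) centered on
the target cytosine passes through three convolution layers (256 kernels of
size 10, ReLU), non-overlapping max pooling (step 20), batch normalization
and dropout 0.5, a linear projection to the model width, then a stack of
eight post-norm transformer encoder layers (self-attention + position-wise
feed-forward, residual connections, layer norm, dropout 0.1, learned
positional embeddings). The module output is the mean of the final token
features. Minus-strand targets are encoded on the reverse complement so
the CG motif always reads 5′→3′.

**CpG module.** The K×N matrix of cluster levels at the K catalog CpGs
nearest the target (K/2 per side, borrowing at chromosome ends; K = 100
full scale; the target itself excluded) is processed per cluster by one
shared 1-D CNN. Undefined levels carry the sentinel −1 in the input
surface; internally the CNN reads two channels per cluster — the level and
a defined-flag derived from it — because at low coverage a convolution
over raw sentinels cannot represent the masked averaging the sparse
profiles require. The element-wise mean of the per-cluster feature
matrices feeds a position-wise transformer over the K positions; the
feature at the target position (index K/2, the boundary between upstream
and downstream neighbors) is added to each cluster's feature at that
position, and the resulting N tokens pass through the cluster-wise
transformer. The head consumes the N output tokens concatenated, so the
fused input width scales with the number of clusters and is re-sized when
a model is fine-tuned onto a dataset with a different cluster count. This
cluster-resolved readout (rather than pooling over clusters) is what lets
the per-cell output weights select their own cluster's features.

**Head and loss.** The concatenated module outputs pass through a hidden
layer (768 units full scale), dropout 0.1, and a sigmoid output layer with
one unit per cell. Training minimizes mean binary cross-entropy over
observed (cell, site) entries only; labels at unobserved positions are
multiplied by an exact zero before the reduction, so they cannot influence
the loss or any gradient (asserted bitwise in tests).

**Training.** CpG sites are split by chromosome into train / validation /
test (chr1–20 / chr21 / chr22 for human data; s1–s3 / s4 / s5 for the
synthetic genomes). Optimization is mini-batch Adam; early stopping
monitors validation AUPRC with a stated patience and the best-epoch weights
are restored. Every stochastic choice (initialization, shuffling, dropout)
draws from one seeded generator, so training is bit-reproducible.

**Fine-tuning.** All weights whose shapes are preserved transfer from a
pre-trained model; the output layer (width = number of cells) and any
cluster-count-dependent shapes (cluster positional embedding, head input)
are freshly initialized. Zero-epoch fine-tuning leaves transferable
weights bit-identical.

**Numerical core.** The network runs on a small reverse-mode autograd
engine over numpy (`scmeth.nn`) implementing exactly the required
operations; gradients are validated against central finite differences.
Working precision is float32 (switchable; gradient checks run in float64).

## Baselines and ablations

* **Cluster model:** a cell's missing site is imputed with its cluster's
  read-weighted level at that site. When scoring held-out *observed*
  entries, the target cell's own read is removed from the aggregate
  (cluster and global) to avoid leakage. Fallbacks: cluster level → global
  level → 0.5.
* **CNN model:** identical architecture with every transformer stack
  replaced by convolutions of matching width (`encoder_kind="cnn_only"`);
  the DNA branch then summarizes with the center token, keeping its
  receptive field finite (tested by distal-perturbation invariance).
* **Ablations:** `module_mode="dna_only"` / `"cpg_only"` drop the other
  branch entirely (tested by input-perturbation invariance).

## Evaluation

The unit of evaluation is the observed (cell, site) entry on the held-out
chromosome; the metric is AUPRC with methylated (1) as the positive class
(the majority class in CpG context). Reports stratify by site variability
— the binomial variance p(1−p) of observed states across cells, in deciles
over sites with ≥2 observations — and by any BED annotation (0-based
half-open).

**Imputation quality score.** For each imputed entry, the mean absolute
difference between the target's predicted level and the predictions at its
five upstream and five downstream catalog neighbors in the same cell
(deficits borrowed across the target near chromosome ends). Filtering
keeps entries with score strictly below a threshold; nested thresholds
yield nested retained sets.

**Downsampling harness.** Observed entries are subsampled uniformly:
each entry draws one uniform variate from the seeded stream and the
round(rate·n) smallest are retained, so counts are exact and retained sets
are nested across rates under a shared seed. A per-site mode removes whole
sites instead.

## Synthetic data

The generator produces a study in which every other module is testable
without downloads:

* **Genome:** random ACGT with CG suppressed in the background, CpGs
  planted at density 0.004/bp (five 200 kb chromosomes → ~4,400 CpGs), and
  two hypomethylation motifs planted at recorded positions (40 instances
  each per chromosome) with distinct logit effects (−4.0 and −1.5) — only
  a sequence-aware model can tell the two apart.
* **Methylome:** per 20 kb block a baseline logit shared across clusters,
  drawn Uniform(0.5, 2.0) (a mostly-methylated genome, matching CpG
  methylomes); per cluster, 10 hypomethylated blocks of 15 kb shifted by
  −3.5 (synthetic cell-type DMRs); motif effects added on the logit scale.
  Per-(cluster, site) probability = logistic of the sum.
* **Cells:** 200 cells in 4 balanced clusters; each cell draws Bernoulli
  states from its cluster's probabilities; each (cell, site) entry is
  observed with the coverage rate (default 0.10 at this genome scale; the
  real technologies observe ~5% of a genome 25,000× larger); read depth is
  1 + Poisson(0.3) with all reads concordant with the drawn state, so
  state calling recovers the simulation exactly. An optional discordance
  rate plants mixed-read records to exercise the exclusion rule.

Defaults were chosen so that the planted cluster structure is recoverable
from the full-coverage bin matrix (ARI = 1 across seeds) while per-site
cluster coverage stays realistically sparse (~5 reads per cluster-site).
What passing tests show is that the implementation learns the planted
generative structure — motif effects, block baselines, cluster membership
— at desk scale; they do not certify performance on real methylomes, which
add mapping bias, bisulfite conversion error, covariate structure and
20,000-fold more sites.

## Scaled study conditions

The desk-scale model (`ModelConfig.scaled`) uses L = 128, K = 16, 32
convolution kernels of size 8, pool step 16, two transformer layers of
width 64 (4 heads, FFN 128), head width 128, Adam at 2e-3, batch 64, up to
25 epochs with patience 5. One training takes ~2 minutes on one CPU. At
these sizes the full model exceeds the cluster baseline on motif-affected
held-out sites and each single-branch ablation on its disadvantaged site
class, across seeds.

The coverage-robustness study mirrors the full-scale procedure of
pre-training once and fine-tuning per condition: a model is pre-trained at
full coverage on an independent synthetic dataset and fine-tuned on the
target dataset downsampled at each rate. The study starts from a denser
synthetic reference (coverage 0.5), so that a 0.1 downsampling rate lands
at 5% effective coverage — the regime real single-cell methylomes occupy —
and a cell still retains a few hundred observations. This matters because
the per-cell output weights are estimated only from that cell's observed
entries: at ~40 observations per cell (the 1%-effective regime) no
optimization variant we tested recovers per-cell cluster identity even
though a Bayes computation shows the information is present, and the
imputed data then fails to re-cluster. The acceptance grid reports this
collapse at rate 0.02 honestly rather than asserting it away.

## Known limitations

* The DNA module sees the reference sequence only; sample-specific
  variants are invisible.
* The quality score assumes local methylation smoothness and over-filters
  genuinely heterogeneous regions.
* Entry-level AUPRC weights well-covered sites more heavily than a
  per-site average would.
* The desk-scale model underfits regimes with fewer than ~100 observations
  per cell (see above); the full-scale setting is not affected because the
  genome is 25,000× larger.
* CpH contexts are out of scope; the state caller filters to CpG.
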