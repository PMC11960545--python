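# scmeth

Imputation of single-cell DNA methylation states with a sequence- and
cluster-aware neural network.

Single-nucleus bisulfite technologies (snmC-seq, snmC-seq2, sn-m3C-seq,
snmCAT-seq, scNMT-seq) cover only ~5% of CpG sites per cell, at one or two
reads each. `scmeth` predicts the methylation state of every CpG in every
cell from two complementary signals:

* **DNA module** — a CNN (256 kernels of size 10, ReLU, max-pool step 20,
  batch norm, dropout 0.5) followed by an eight-layer transformer encoder
  reads a 2 kb one-hot window around the target CpG and learns methylation
  motifs and their long-range interactions.
* **CpG module** — for the K = 100 CpGs nearest the target (target
  excluded), the methylation level of each pre-defined cell cluster
  (reads methylated / reads total within the cluster) forms a K×N matrix;
  a shared CNN per cluster, a position-wise transformer over the K
  positions, and a cluster-wise transformer over the N clusters extract
  the local methylation context per cluster.

The two feature vectors are concatenated into a fully connected head
(768 hidden units, dropout, sigmoid) with **one output unit per cell**.
Training minimizes masked binary cross-entropy: only (cell, site) entries
whose binary state was measured contribute, where a state is 1 if all
mapped reads support methylation, 0 if none do, and sites with
disagreeing reads are excluded. CpG sites are split by chromosome into
training (chr1–20), validation (chr21) and test (chr22) sets.

The package also provides the comparison models (cluster-mean imputation;
a CNN-only variant with transformers replaced by convolutions; single-
branch ablations), entry-level AUPRC evaluation stratified by site
variability and by BED annotations, the per-entry imputation quality score
(mean |Δp| to the 10 nearest neighbors in the same cell, lower = more
trustworthy) with threshold filtering, a downsampling harness, ARI-based
cluster-recovery evaluation, imputed-ALLC export (each predicted state
becomes one supporting read), and a fully specified synthetic-data
generator so the whole method is exercisable end to end with no downloads.

The neural core runs on a compact reverse-mode autograd engine over numpy
(`scmeth.nn`) whose gradients are verified against finite differences in
the test suite.

## Worked example

Desk-scale study: 200 cells in 4 clusters over a 1 Mb synthetic genome
(~4,400 CpGs, 10% of sites observed per cell), scaled model (2 transformer
layers, width 64):

```python
from dataclasses import replace
from scmeth import SyntheticConfig, train
from scmeth.baselines import cluster_prediction_matrix
from scmeth.pipeline import prepare_study, held_out_auprc

study = prepare_study(SyntheticConfig(seed=1))
print(f"clustering ARI vs planted clusters: {study.clustering_ari:.3f}")

model, history = train(study.model_config, study.train_set, study.val_set)
pred = model.predict_all(study.test_set)
print(f"full model test AUPRC:      {held_out_auprc(study, pred):.4f}")

baseline = cluster_prediction_matrix(
    study.profile, study.assignment, study.cells,
    site_rows=study.test_set.site_rows, exclude_states=study.test_states)
print(f"cluster baseline test AUPRC: {held_out_auprc(study, baseline):.4f}")
```

Output (about 2.5 minutes on one CPU):

```
clustering ARI vs planted clusters: 1.000
full model test AUPRC:      0.8054
cluster baseline test AUPRC: 0.7929
```

The AUPRC is computed over the 17,746 observed (cell, site) entries on the
held-out chromosome. ARI = 1.0 means PCA + k-means on 20 kb bin levels
recovered the planted cell clusters exactly. The full model's advantage
concentrates where it should: on motif-affected sites (the generator
plants two hypomethylation motifs with different effect sizes) the full
model reaches AUPRC 0.452 against 0.413 for the cluster baseline and 0.299
for the profile-only ablation, which cannot see sequence. Tightening the
imputation-quality filter raises the test AUPRC monotonically (0.805
unfiltered → 0.813 at threshold 0.1, retaining 11,854 of 17,746 entries).

The same flow is available from the shell:

```bash
scmeth simulate --seed 1 --out run/data
scmeth cluster --allc-dir run/data/allc --fasta run/data/genome.fa \
       --bin-size 20000 --k 4 --seed 1 --out run/clusters.tsv
scmeth ari --a run/clusters.tsv --b run/data/true_clusters.tsv
scmeth run --config pipeline.yaml --out run/   # end-to-end with manifest
```

## Layout

| module | contents |
|---|---|
| `scmeth.io` | ALLC/FASTA reading and writing, binary state calling, chromosome splits, imputed-ALLC export |
| `scmeth.clustering` | bin matrices, PCA+k-means cell clustering, cluster profiles, ARI |
| `scmeth.encoding` | DNA windows, neighbor tensors, training examples |
| `scmeth.nn` | the autograd engine and layers |
| `scmeth.model` | model configuration, architecture, masked loss, training, fine-tuning, checkpoints |
| `scmeth.baselines` | cluster-mean imputation, CNN-only configuration |
| `scmeth.evaluation` | AUPRC, variability/annotation strata, quality scores, filtering, downsampling |
| `scmeth.simulate` | the synthetic-data generator with ground truth |
| `scmeth.pipeline` / `scmeth.cli` | end-to-end orchestration and the `scmeth` command |

See `docs/methods.md` for the model, the synthetic study conditions, and
known limitations.
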