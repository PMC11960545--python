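"""The two-branch methylation imputation model and its training loop.

The DNA module reads an L x 4 one-hot window through a three-layer CNN
(256 kernels of size 10, ReLU), non-overlapping max pooling (step 20),
batch normalization and dropout (0.5), then a stack of transformer encoder
layers; its output is the mean of the final token features (or the center
token for the CNN-only encoder variant).

The CpG module reads the K x N neighbor-level matrix: one shared 1-D CNN
per cluster produces a feature matrix per cluster, the element-wise mean
across clusters feeds a position-wise transformer over the K positions, and
the feature at the target position, joined with each cluster's feature at
that position, feeds a cluster-wise transformer over the N clusters.

The fused head concatenates both module outputs, applies a hidden layer of
768 units, dropout, and a sigmoid output with one unit per cell.  Training
minimizes binary cross-entropy over observed (cell, site) entries only —
unobserved labels can never influence the loss or its gradients.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np

from . import nn
from .encoding import ExampleSet
from .io import SiteCatalog

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


class TrainingDiverged(RuntimeError):
    pass


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Defaults mirror the full-scale setting (2 kb windows, 100 neighbors,
    256 conv kernels of size 10, pool step 20, eight transformer layers,
    768-unit head).  ``scaled()`` returns a desk-scale variant that trains
    in minutes on one CPU.
    """

    n_cells: int = 0
    n_clusters: int = 1
    L: int = 2000
    K: int = 100
    conv_layers: int = 3
    conv_kernels: int = 256
    kernel_size: int = 10
    pool_step: int = 20
    conv_dropout: float = 0.5
    n_transformer_layers: int = 8
    n_heads: int = 8
    model_dim: int = 256
    ffn_dim: int = 1024
    transformer_dropout: float = 0.1
    head_hidden: int = 768
    head_dropout: float = 0.1
    module_mode: str = "both"  # both | dna_only | cpg_only
    encoder_kind: str = "transformer"  # transformer | cnn_only
    positional: bool = True
    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 20
    patience: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.module_mode not in ("both", "dna_only", "cpg_only"):
            raise ValueError(f"bad module_mode {self.module_mode!r}")
        if self.encoder_kind not in ("transformer", "cnn_only"):
            raise ValueError(f"bad encoder_kind {self.encoder_kind!r}")
        for name in ("L", "K", "conv_layers", "conv_kernels", "kernel_size",
                     "pool_step", "n_transformer_layers", "n_heads",
                     "model_dim", "ffn_dim", "head_hidden", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("conv_dropout", "transformer_dropout", "head_dropout"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0,1)")
        if self.L % 2 or self.K % 2:
            raise ValueError("L and K must be even")

    @classmethod
    def scaled(cls, n_cells: int, n_clusters: int, **overrides) -> "ModelConfig":
        """Desk-scale configuration used throughout the synthetic study."""
        base = dict(
            n_cells=n_cells, n_clusters=n_clusters, L=128, K=16,
            conv_kernels=32, kernel_size=8, pool_step=16,
            n_transformer_layers=2, n_heads=4, model_dim=64, ffn_dim=128,
            head_hidden=128, learning_rate=2e-3, batch_size=64,
            max_epochs=25, patience=5,
        )
        base.update(overrides)
        return cls(**base)


class _DnaEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.convs = []
        c_in = 4
        for _ in range(cfg.conv_layers):
            self.convs.append(nn.Conv1d(c_in, cfg.conv_kernels, cfg.kernel_size,
                                        rng))
            c_in = cfg.conv_kernels
        self.pool_step = cfg.pool_step
        self.bn = nn.BatchNorm(cfg.conv_kernels)
        self.drop = nn.Dropout(cfg.conv_dropout, rng)
        self.proj = nn.Linear(cfg.conv_kernels, cfg.model_dim, rng)
        n_tokens = cfg.L // cfg.pool_step
        self.cnn_only = cfg.encoder_kind == "cnn_only"
        if self.cnn_only:
            # transformer stack replaced by convolutions of matching width
            self.encoder_convs = [
                nn.Conv1d(cfg.model_dim, cfg.model_dim, 3, rng)
                for _ in range(cfg.n_transformer_layers)]
            self.center = n_tokens // 2
        else:
            self.encoder = nn.TransformerEncoder(
                cfg.n_transformer_layers, cfg.model_dim, cfg.n_heads,
                cfg.ffn_dim, cfg.transformer_dropout, n_tokens, rng,
                positional=cfg.positional)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        for conv in self.convs:
            x = nn.relu(conv(x))
        x = nn.maxpool1d(x, self.pool_step)
        x = self.bn(x)
        x = self.drop(x)
        x = self.proj(x)
        if self.cnn_only:
            for conv in self.encoder_convs:
                x = nn.relu(conv(x))
            return x[:, self.center, :]
        x = self.encoder(x)
        return x.mean(axis=1)


class _CpgEncoder(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.n_clusters = cfg.n_clusters
        self.convs = []
        # two input channels per cluster: the level (sentinel -1 where the
        # cluster has no reads) and a defined-flag, so sparse profiles can
        # be averaged instead of polluted by sentinels
        c_in = 2
        for _ in range(cfg.conv_layers):
            self.convs.append(nn.Conv1d(c_in, cfg.conv_kernels, cfg.kernel_size,
                                        rng))
            c_in = cfg.conv_kernels
        self.proj = nn.Linear(cfg.conv_kernels, cfg.model_dim, rng)
        self.cluster_proj = nn.Linear(cfg.conv_kernels, cfg.model_dim, rng)
        self.cnn_only = cfg.encoder_kind == "cnn_only"
        if self.cnn_only:
            self.pos_convs = [nn.Conv1d(cfg.model_dim, cfg.model_dim, 3, rng)
                              for _ in range(cfg.n_transformer_layers)]
            self.clu_convs = [nn.Conv1d(cfg.model_dim, cfg.model_dim, 3, rng)
                              for _ in range(cfg.n_transformer_layers)]
        else:
            self.position_encoder = nn.TransformerEncoder(
                cfg.n_transformer_layers, cfg.model_dim, cfg.n_heads,
                cfg.ffn_dim, cfg.transformer_dropout, cfg.K, rng,
                positional=cfg.positional)
            self.cluster_encoder = nn.TransformerEncoder(
                cfg.n_transformer_layers, cfg.model_dim, cfg.n_heads,
                cfg.ffn_dim, cfg.transformer_dropout, cfg.n_clusters, rng,
                positional=cfg.positional)

    def __call__(self, x: nn.Tensor, target_row_index: int) -> nn.Tensor:
        bsz, k, n = x.shape
        # shared CNN per cluster: fold clusters into the batch axis
        z = nn.reshape(nn.transpose(x, (0, 2, 1)), (bsz * n, k, 1))
        defined = nn.Tensor((z.data >= 0).astype(z.data.dtype))
        z = nn.concat([z, defined], axis=-1)
        for conv in self.convs:
            z = nn.relu(conv(z))
        feats = nn.reshape(z, (bsz, n, k, -1))  # (B, N, K, C)
        mean_feats = feats.mean(axis=1)  # (B, K, C)
        pos_tokens = self.proj(mean_feats)
        if self.cnn_only:
            for conv in self.pos_convs:
                pos_tokens = nn.relu(conv(pos_tokens))
        else:
            pos_tokens = self.position_encoder(pos_tokens)
        target_feat = pos_tokens[:, target_row_index, :]  # (B, D)
        # per-cluster features at the target position, joined with the
        # position-wise target feature
        cluster_tokens = self.cluster_proj(feats[:, :, target_row_index, :])
        cluster_tokens = cluster_tokens + nn.reshape(target_feat, (bsz, 1, -1))
        if self.cnn_only:
            for conv in self.clu_convs:
                cluster_tokens = nn.relu(conv(cluster_tokens))
        else:
            cluster_tokens = self.cluster_encoder(cluster_tokens)
        # cluster-resolved output: the head's input width scales with the
        # number of clusters (re-sized on fine-tuning)
        return nn.reshape(cluster_tokens, (bsz, n * cluster_tokens.shape[-1]))


class _Network(nn.Module):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.mode = cfg.module_mode
        d_in = 0
        if self.mode in ("both", "dna_only"):
            self.dna = _DnaEncoder(cfg, rng)
            d_in += cfg.model_dim
        if self.mode in ("both", "cpg_only"):
            self.cpg = _CpgEncoder(cfg, rng)
            d_in += cfg.model_dim * cfg.n_clusters
        self.hidden = nn.Linear(d_in, cfg.head_hidden, rng)
        self.head_drop = nn.Dropout(cfg.head_dropout, rng)
        self.out = nn.Linear(cfg.head_hidden, cfg.n_cells, rng)

    def __call__(self, dna: np.ndarray, neighbors: np.ndarray,
                 target_row_index: int) -> nn.Tensor:
        parts = []
        if self.mode in ("both", "dna_only"):
            parts.append(self.dna(nn.Tensor(dna)))
        if self.mode in ("both", "cpg_only"):
            parts.append(self.cpg(nn.Tensor(neighbors), target_row_index))
        x = parts[0] if len(parts) == 1 else nn.concat(parts, axis=-1)
        x = self.head_drop(nn.relu(self.hidden(x)))
        return nn.sigmoid(self.out(x))


def masked_loss(probs: nn.Tensor, labels: np.ndarray, mask: np.ndarray,
                eps: float = 1e-12) -> nn.Tensor:
    """Mean binary cross-entropy over observed entries only.

    Labels at mask-false positions are multiplied by an exact zero before
    the reduction, so they cannot move the loss or any gradient.  Returns 0
    when the mask is all false.
    """
    labels = np.asarray(labels, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if probs.shape != labels.shape or labels.shape != mask.shape:
        raise ValueError("shape mismatch between probabilities, labels, mask")
    if np.any((labels[mask] != 0) & (labels[mask] != 1)):
        raise ValueError("observed labels must be 0 or 1")
    count = int(mask.sum())
    if count == 0:
        logger.debug("masked_loss: batch with empty mask, loss defined as 0")
        return nn.Tensor(0.0)
    m = mask.astype(np.float64)
    y = labels * m  # zero out unobserved labels exactly
    p = probs
    bce = -(nn.mul(nn.log(p + eps), y) + nn.mul(nn.log((1.0 - p) + eps), m - y))
    return nn.mul(nn.tsum(nn.mul(bce, m)), 1.0 / count)


class PredictionMatrix:
    """Cells x sites methylation probabilities with provenance flags.

    ``observed`` marks entries whose binary state was measured;
    ``retained`` marks entries surviving quality-score filtering (all True
    until a filter is applied).
    """

    def __init__(self, cells: Sequence[str], catalog: SiteCatalog,
                 probs: np.ndarray, observed: np.ndarray | None = None,
                 retained: np.ndarray | None = None):
        probs = np.asarray(probs, dtype=np.float64)
        if probs.shape != (len(cells), len(catalog)):
            raise ValueError("prediction matrix shape mismatch")
        if np.any(probs < 0) or np.any(probs > 1):
            raise ValueError("probabilities outside [0,1]")
        self.cells = list(cells)
        self.catalog = catalog
        self.probs = probs
        self.observed = (np.zeros(probs.shape, dtype=bool)
                         if observed is None else np.asarray(observed, bool))
        self.retained = (np.ones(probs.shape, dtype=bool)
                         if retained is None else np.asarray(retained, bool))

    def with_retained(self, retained: np.ndarray) -> "PredictionMatrix":
        return PredictionMatrix(self.cells, self.catalog, self.probs,
                                self.observed, retained)

    def save(self, path) -> None:
        np.savez(path, cells=np.array(self.cells, dtype=str),
                 chrom=self.catalog.chrom.astype(str), pos=self.catalog.pos,
                 strand=self.catalog.strand.astype(str), probs=self.probs,
                 observed=self.observed, retained=self.retained)

    @classmethod
    def load(cls, path) -> "PredictionMatrix":
        z = np.load(path)
        cat = SiteCatalog(z["chrom"].astype(object), z["pos"],
                          z["strand"].astype(object))
        return cls([str(c) for c in z["cells"]], cat, z["probs"],
                   z["observed"], z["retained"])


class ImputationModel:
    """A configured network plus its training metadata and RNG."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.network = _Network(config, self.rng)
        self.metadata = {"epochs_run": 0, "best_val_auprc": None}

    # -- forward -----------------------------------------------------------

    def forward(self, dna: np.ndarray, neighbors: np.ndarray,
                target_row_index: int, training: bool = False) -> nn.Tensor:
        self.network.set_training(training)
        if dna.shape[1] != self.config.L:
            raise ValueError(f"window length {dna.shape[1]} != L={self.config.L}")
        if neighbors.shape[1:] != (self.config.K, self.config.n_clusters):
            raise ValueError("neighbor tensor shape mismatch")
        return self.network(dna, neighbors, target_row_index)

    def predict(self, examples: ExampleSet, batch_size: int = 256) -> np.ndarray:
        """(n_sites, n_cells) probabilities, deterministic (dropout off)."""
        outs = []
        with nn.no_grad():
            for start in range(0, len(examples), batch_size):
                sel = slice(start, start + batch_size)
                p = self.forward(examples.dna[sel], examples.neighbors[sel],
                                 examples.target_row_index, training=False)
                outs.append(p.data)
        return np.concatenate(outs, axis=0) if outs else np.empty(
            (0, self.config.n_cells))

    def predict_all(self, examples: ExampleSet,
                    observed: np.ndarray | None = None) -> PredictionMatrix:
        """PredictionMatrix over the examples' sites for every cell."""
        probs = self.predict(examples).T  # (n_cells, n_sites)
        cat = examples.catalog
        rows = examples.site_rows
        sub = SiteCatalog(cat.chrom[rows], cat.pos[rows], cat.strand[rows])
        obs = examples.mask.T if observed is None else observed
        return PredictionMatrix(examples.cells, sub, np.clip(probs, 0, 1), obs)

    # -- training ----------------------------------------------------------

    def fit(self, train_set: ExampleSet, val_set: ExampleSet | None = None,
            log_path=None) -> list:
        """Mini-batch Adam on the masked loss with early stopping on
        validation AUPRC; restores the best-epoch weights.  Returns the
        epoch history."""
        from .evaluation import auprc  # local import to avoid a cycle

        cfg = self.config
        if len(train_set) == 0:
            raise ValueError("empty training stream")
        opt = nn.Adam(self.network.parameters(), lr=cfg.learning_rate)
        history = []
        best_metric, best_state, bad_epochs = -np.inf, None, 0
        for epoch in range(cfg.max_epochs):
            losses = []
            for dna, nb, labels, mask in train_set.batches(cfg.batch_size,
                                                           self.rng):
                if not mask.any():
                    continue
                probs = self.forward(dna, nb, train_set.target_row_index,
                                     training=True)
                loss = masked_loss(probs, labels, mask)
                if not np.isfinite(loss.data):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {epoch}: {loss.data}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            record = {"epoch": epoch, "train_loss": float(np.mean(losses))}
            if val_set is not None and len(val_set):
                probs = self.predict(val_set)
                m = val_set.mask
                labels = val_set.labels[m]
                record["val_auprc"] = (
                    float(auprc(labels, probs[m]))
                    if len(np.unique(labels)) == 2 else float("nan"))
            history.append(record)
            logger.info("epoch %d: %s", epoch, record)
            metric = record.get("val_auprc")
            if metric is not None and np.isfinite(metric):
                if metric > best_metric:
                    best_metric, bad_epochs = metric, 0
                    best_state = self.network.state_dict()
                else:
                    bad_epochs += 1
                    if bad_epochs >= cfg.patience:
                        logger.info("early stop at epoch %d", epoch)
                        break
        if best_state is not None:
            self.network.load_state_dict(best_state)
            self.metadata["best_val_auprc"] = best_metric
        self.metadata["epochs_run"] = len(history)
        if log_path is not None:
            import pandas as pd
            pd.DataFrame(history).to_csv(log_path, sep="\t", index=False)
        return history

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        state = self.network.state_dict()
        np.savez(path,
                 __config__=json.dumps(asdict(self.config)),
                 __metadata__=json.dumps(self.metadata),
                 __version__=CHECKPOINT_VERSION,
                 **state)

    @classmethod
    def load(cls, path) -> "ImputationModel":
        z = np.load(path, allow_pickle=True)
        cfg = ModelConfig(**json.loads(str(z["__config__"])))
        model = cls(cfg)
        state = {k: z[k] for k in z.files if not k.startswith("__")}
        model.network.load_state_dict(state)
        model.metadata = json.loads(str(z["__metadata__"]))
        return model


def train(config: ModelConfig, train_set: ExampleSet,
          val_set: ExampleSet | None = None, log_path=None):
    """Train a fresh model; returns (model, history)."""
    model = ImputationModel(config)
    history = model.fit(train_set, val_set, log_path)
    return model, history


NON_TRANSFERABLE = ("out.",)  # head output layer: width = n_cells


def fine_tune(pretrained: ImputationModel, config: ModelConfig,
              train_set: ExampleSet | None = None,
              val_set: ExampleSet | None = None, log_path=None):
    """Initialize a model for a new dataset from a pre-trained one.

    ``config`` may change n_cells and n_clusters (the output layer and the
    cluster-wise positional embedding are freshly initialized when their
    shapes change); L and K must match the pre-trained model.  With
    max_epochs=0 the transferable weights stay bit-identical.
    """
    pcfg = pretrained.config
    if config.L != pcfg.L or config.K != pcfg.K:
        raise ValueError("fine-tuning requires matching L and K")
    model = ImputationModel(config)
    source = pretrained.network.state_dict()
    transferable = {
        k: v for k, v in source.items()
        if not any(k.startswith(p) or k.split("buffer:")[-1].startswith(p)
                   for p in NON_TRANSFERABLE)
    }
    skipped = model.network.load_state_dict(transferable, strict=False)
    if skipped:
        logger.info("fine_tune: re-initialized %s", skipped)
    history = []
    if config.max_epochs > 0:
        if train_set is None:
            raise ValueError("fine-tuning with max_epochs > 0 needs data")
        history = model.fit(train_set, val_set, log_path)
    return model, history
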