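"""End-to-end orchestration of the standard analysis flows.

Two entry points:

* :func:`run_pipeline` executes the configured stages (simulate -> bin ->
  cluster -> profile -> train -> impute -> score -> filter -> evaluate) in
  dependency order, writing every artifact plus a machine-readable manifest
  (config hash, seeds, artifact paths, metrics) to a run directory.
* :func:`downsampling_study` mirrors the coverage-robustness experiment:
  a model is pre-trained at full coverage on an independent synthetic
  dataset, then fine-tuned on the target dataset downsampled at each rate;
  imputation quality (AUPRC) and cluster recovery (ARI against the
  reference partition) are measured per rate alongside the no-imputation
  baseline.

Every stage is a pure function of (inputs, config, seed): rerunning with an
identical config reproduces identical metrics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .baselines import cluster_prediction_matrix
from .clustering import (ClusterAssignment, ClusterProfile,
                         adjusted_rand_index, bin_matrix_from_predictions,
                         cluster_cells, compute_bin_matrix)
from .encoding import make_examples
from .evaluation import auprc, downsample, evaluate, quality_scores
from .io import ConfigError, split_sites
from .model import ImputationModel, ModelConfig, fine_tune, train
from .simulate import SyntheticConfig, SyntheticDataset, simulate

logger = logging.getLogger(__name__)

DEFAULT_BIN_SIZE = 20_000  # synthetic genomes; 100 kb for full-size ones
DEFAULT_THRESHOLDS = (0.4, 0.3, 0.2, 0.1)


def config_hash(config: dict) -> str:
    """Stable hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class Study:
    """A prepared synthetic study: dataset, inferred clusters, profiles and
    batch-ready example sets on the train/val/test chromosome split."""

    dataset: SyntheticDataset
    assignment: ClusterAssignment
    clustering_ari: float
    profile: ClusterProfile
    model_config: ModelConfig
    train_set: object
    val_set: object
    test_set: object
    test_states: object
    bin_size: int

    @property
    def cells(self):
        return self.dataset.cells


def prepare_study(synth_config: SyntheticConfig,
                  model_overrides: dict | None = None,
                  bin_size: int = DEFAULT_BIN_SIZE,
                  states=None) -> Study:
    """Simulate, cluster, profile and encode a synthetic study.

    ``states`` overrides the binary state table used for profiles and
    training labels (e.g. a downsampled table); clustering always runs on
    the raw call tables so the partition matches the full-coverage data.
    """
    ds = simulate(synth_config)
    bm = compute_bin_matrix(ds.tables, ds.genome, bin_size=bin_size)
    assignment = cluster_cells(bm, synth_config.n_clusters,
                               seed=synth_config.seed)
    ari = adjusted_rand_index(assignment, ds.planted_assignment())
    used_states = ds.states if states is None else states
    profile = ClusterProfile.from_states(used_states, assignment, ds.catalog)
    mcfg = ModelConfig.scaled(synth_config.n_cells, synth_config.n_clusters,
                              seed=synth_config.seed,
                              **(model_overrides or {}))
    tr, va, te = split_sites(ds.catalog, synth_config.split)
    kw = dict(k=mcfg.K, length=mcfg.L)
    train_set = make_examples(used_states, profile, ds.genome, ds.cells,
                              site_rows=tr, **kw)
    val_set = make_examples(used_states, profile, ds.genome, ds.cells,
                            site_rows=va, **kw)
    test_set = make_examples(ds.states, profile, ds.genome, ds.cells,
                             site_rows=te, **kw)
    test_states = ds.states.subset_chroms(list(synth_config.split.test))
    return Study(ds, assignment, ari, profile, mcfg, train_set, val_set,
                 test_set, test_states, bin_size)


def held_out_auprc(study: Study, pred) -> float:
    """Entry-level AUPRC of a PredictionMatrix on the held-out states."""
    mat, obs = study.test_states.dense(study.cells, pred.catalog)
    rows, cols = np.nonzero(obs)
    return auprc(mat[rows, cols].astype(int), pred.probs[rows, cols])


def imputed_ari(study: Study, model: ImputationModel, states) -> float:
    """Cluster-recovery ARI of clusters re-derived from model-imputed data
    against the planted partition."""
    cfg = study.dataset.config
    all_set = make_examples(states, study.profile, study.dataset.genome,
                            study.cells, site_rows=None,
                            require_observed=False,
                            k=study.model_config.K,
                            length=study.model_config.L)
    pred = model.predict_all(all_set)
    bm = bin_matrix_from_predictions(pred, study.dataset.genome,
                                     bin_size=study.bin_size)
    inferred = cluster_cells(bm, cfg.n_clusters, seed=cfg.seed)
    return adjusted_rand_index(inferred, study.dataset.planted_assignment())


def raw_ari(study: Study, states) -> float:
    """Cluster-recovery ARI from the (possibly downsampled) raw states,
    without imputation: bin levels from the binary entries themselves."""
    from .io import BinaryStateTable
    from .model import PredictionMatrix
    cfg = study.dataset.config
    smat, omat = states.dense(study.cells, study.dataset.catalog)
    probs = np.where(omat, smat.astype(float), 0.0)
    pred = PredictionMatrix(study.cells, study.dataset.catalog, probs,
                            omat, retained=omat)
    bm = bin_matrix_from_predictions(pred, study.dataset.genome,
                                     bin_size=study.bin_size)
    inferred = cluster_cells(bm, cfg.n_clusters, seed=cfg.seed)
    return adjusted_rand_index(inferred, study.dataset.planted_assignment())


def downsampling_study(seed: int, rates=(1.0, 0.1),
                       synth_overrides: dict | None = None,
                       model_overrides: dict | None = None,
                       fine_tune_epochs: int = 30) -> dict:
    """Coverage-robustness experiment at the synthetic desk scale.

    A model is pre-trained from scratch at full coverage on an independent
    synthetic dataset (different genome and cells, same study conditions),
    then fine-tuned on the target dataset downsampled at each rate — the
    same pre-train/fine-tune strategy the full-scale method uses for its
    downsampling analyses.  Returns per-rate test AUPRC, imputed-data
    cluster-recovery ARI, and the no-imputation ARI.
    """
    synth_overrides = synth_overrides or {}
    pre_cfg = SyntheticConfig(seed=seed + 1000, **synth_overrides)
    pre_study = prepare_study(pre_cfg, model_overrides)
    pretrained, _ = train(pre_study.model_config, pre_study.train_set,
                          pre_study.val_set)

    target_cfg = SyntheticConfig(seed=seed, **synth_overrides)
    base_study = prepare_study(target_cfg, model_overrides)
    out = {"seed": seed, "rates": {}}
    for rate in rates:
        states = (base_study.dataset.states if rate == 1.0 else
                  downsample(base_study.dataset.states, rate, seed=seed))
        study = prepare_study(target_cfg, model_overrides, states=states)
        fcfg = replace(study.model_config, max_epochs=fine_tune_epochs,
                       patience=fine_tune_epochs)
        model, _ = fine_tune(pretrained, fcfg, study.train_set, study.val_set)
        out["rates"][rate] = {
            "auprc": held_out_auprc(study, model.predict_all(study.test_set)),
            "imputed_ari": imputed_ari(study, model, states),
            "raw_ari": raw_ari(study, states),
            "n_train_entries": int(len(states)),
        }
    return out


# ---------------------------------------------------------------------------
# configured pipeline
# ---------------------------------------------------------------------------

STAGES = ("simulate", "cluster", "train", "impute", "score", "evaluate")


def run_pipeline(config, out_dir, dry_run: bool = False) -> dict:
    """Run the standard flow described by a YAML/dict config.

    Config keys: ``seed``; ``simulate`` (SyntheticConfig overrides);
    ``cluster`` (bin_size); ``model`` (ModelConfig overrides);
    ``evaluate`` (score thresholds).  Returns the manifest.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    seed = int(config.get("seed", 0))
    if dry_run:
        return {"stages": list(STAGES), "config_hash": config_hash(config)}

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings = {}

    t0 = time.time()
    synth = SyntheticConfig(seed=seed, **config.get("simulate", {}))
    bin_size = int(config.get("cluster", {}).get("bin_size",
                                                 DEFAULT_BIN_SIZE))
    study = prepare_study(synth, config.get("model"), bin_size=bin_size)
    study.dataset.write(out / "data")
    study.assignment.to_tsv(out / "clusters.tsv")
    timings["simulate+cluster"] = round(time.time() - t0, 2)
    logger.info("clustering ARI vs planted: %.3f", study.clustering_ari)

    t0 = time.time()
    model, history = train(study.model_config, study.train_set,
                           study.val_set, log_path=out / "training_log.tsv")
    model.save(out / "model.ckpt.npz")
    timings["train"] = round(time.time() - t0, 2)

    t0 = time.time()
    pred = model.predict_all(study.test_set)
    pred.save(out / "predictions.npz")
    timings["impute"] = round(time.time() - t0, 2)

    t0 = time.time()
    scores = quality_scores(pred)
    np.savez(out / "quality_scores.npz", scores=scores)
    thresholds = tuple(config.get("evaluate", {}).get(
        "thresholds", DEFAULT_THRESHOLDS))
    report = evaluate(pred, study.test_states, thresholds=thresholds,
                      scores=scores)
    report.to_json(out / "eval_report.json")
    timings["score+evaluate"] = round(time.time() - t0, 2)

    cl_pred = cluster_prediction_matrix(
        study.profile, study.assignment, study.cells,
        site_rows=study.test_set.site_rows,
        exclude_states=study.test_states)
    manifest = {
        "config_hash": config_hash(config),
        "seed": seed,
        "stages": list(STAGES),
        "timings_s": timings,
        "total_s": round(time.time() - t_start, 2),
        "artifacts": {
            "data": str(out / "data"),
            "clusters": str(out / "clusters.tsv"),
            "model": str(out / "model.ckpt.npz"),
            "predictions": str(out / "predictions.npz"),
            "eval_report": str(out / "eval_report.json"),
        },
        "metrics": {
            "clustering_ari": study.clustering_ari,
            "epochs_run": model.metadata["epochs_run"],
            "best_val_auprc": model.metadata["best_val_auprc"],
            "test_auprc": report.overall_auprc,
            "cluster_baseline_auprc": held_out_auprc(study, cl_pred),
            "n_test_entries": report.n_entries,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest
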