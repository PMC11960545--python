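"""Comparison models: cluster-mean imputation and the CNN-only variant.

The cluster model imputes a cell's missing CpG state with the read-weighted
methylation level of that CpG across the cells of the same cluster.  When
the prediction is evaluated at an entry whose own reads are part of the
aggregate (a held-out observed entry), those reads are excluded from the
numerator and denominator to avoid leakage.  A cluster with no coverage at
the site falls back to the across-all-cells level, and finally to 0.5.

The CNN-only variant keeps the full architecture but swaps every
transformer stack for convolutional layers of matching width; it is reached
purely through configuration (``encoder_kind="cnn_only"``).
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .clustering import ClusterAssignment, ClusterProfile
from .io import ConfigError, SiteCatalog
from .model import ModelConfig, PredictionMatrix


def cluster_impute(profile: ClusterProfile, assignment: ClusterAssignment,
                   site_row: int, cell_id: str) -> float:
    """The cluster-mean level for one (cell, site); NaN when the cluster has
    no reads at the site (callers apply the global fallback)."""
    if cell_id not in assignment.labels:
        raise ConfigError(f"unknown cell {cell_id!r}")
    return profile.level(assignment.labels[cell_id], site_row)


def cluster_prediction_matrix(profile: ClusterProfile,
                              assignment: ClusterAssignment,
                              cells: Sequence[str],
                              site_rows: np.ndarray | None = None,
                              exclude_states=None) -> PredictionMatrix:
    """Cluster-model predictions for every (cell, site).

    ``exclude_states`` is a BinaryStateTable of entries to evaluate: each
    observed entry's own contribution (its state, counted as one read) is
    removed from its cluster aggregate before the level is formed, assuming
    the profile was built with ``ClusterProfile.from_states`` on a table
    containing those entries.  Fallback chain: cluster level -> global
    level -> 0.5.
    """
    cells = list(cells)
    catalog = profile.catalog
    if site_rows is None:
        site_rows = np.arange(len(catalog))
    site_rows = np.asarray(site_rows, dtype=np.int64)
    labels = [assignment.labels[c] for c in cells]
    pos_of = {lab: i for i, lab in enumerate(profile.cluster_labels)}
    k_of_cell = np.asarray([pos_of[lab] for lab in labels], dtype=np.int64)

    mc = profile.mc_sum[:, site_rows].astype(np.float64)
    cov = profile.cov_sum[:, site_rows].astype(np.float64)
    # per-cell copies of that cell's cluster row
    mc_cell = mc[k_of_cell]  # (n_cells, n_sites)
    cov_cell = cov[k_of_cell]
    observed = np.zeros(mc_cell.shape, dtype=bool)

    if exclude_states is not None:
        f = exclude_states.frame
        cell_idx = {c: i for i, c in enumerate(cells)}
        rows = np.fromiter((cell_idx[c] for c in f["cell"]), dtype=np.int64,
                           count=len(f))
        cols_full = catalog.lookup(f["chrom"].to_numpy(), f["pos"].to_numpy(),
                                   f["strand"].to_numpy())
        col_map = {int(r): i for i, r in enumerate(site_rows)}
        keep = np.asarray([int(c) in col_map for c in cols_full], dtype=bool)
        rows = rows[keep]
        cols = np.asarray([col_map[int(c)] for c in cols_full[keep]],
                          dtype=np.int64)
        states = f["state"].to_numpy()[keep].astype(np.float64)
        mc_cell[rows, cols] -= states
        cov_cell[rows, cols] -= 1.0
        observed[rows, cols] = True

    with np.errstate(invalid="ignore", divide="ignore"):
        level = mc_cell / cov_cell
    level[cov_cell <= 0] = np.nan

    gmc = profile.mc_sum[:, site_rows].sum(axis=0).astype(np.float64)
    gcov = profile.cov_sum[:, site_rows].sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        glevel = gmc / gcov
    glevel[gcov <= 0] = np.nan
    glevel_mat = np.broadcast_to(glevel, level.shape).copy()
    if exclude_states is not None:
        # the target cell's own read also leaves the global fallback
        num = gmc[cols] - states
        den = gcov[cols] - 1.0
        with np.errstate(invalid="ignore", divide="ignore"):
            adj = num / den
        adj[den <= 0] = np.nan
        glevel_mat[rows, cols] = adj

    out = np.where(np.isfinite(level), level, glevel_mat)
    out = np.where(np.isfinite(out), out, 0.5)
    sub = SiteCatalog(catalog.chrom[site_rows], catalog.pos[site_rows],
                      catalog.strand[site_rows])
    return PredictionMatrix(cells, sub, np.clip(out, 0.0, 1.0), observed)


def cnn_baseline_config(base: ModelConfig) -> ModelConfig:
    """The CNN-model configuration: identical except the encoders."""
    return replace(base, encoder_kind="cnn_only")
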