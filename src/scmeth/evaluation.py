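"""Evaluation of imputed methylation states.

The primary metric is the area under the precision-recall curve (AUPRC)
over held-out observed (cell, site) entries, with the methylated state (1)
as the positive class.  Evaluation can be stratified by site variability
(the binomial variance p(1-p) of the observed states across cells, split
into deciles) and by arbitrary BED annotations.

Each imputed entry also receives an imputation quality score: the mean
absolute difference between the target CpG's predicted level and the
predictions at its five upstream and five downstream neighboring CpGs in
the same cell.  Lower scores mark more trustworthy entries; filtering keeps
entries with score strictly below a threshold.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score

from .io import BinaryStateTable, ConfigError, SiteCatalog
from .model import PredictionMatrix

logger = logging.getLogger(__name__)


class UndefinedMetric(ValueError):
    """AUPRC requested on a single-class label vector."""


def auprc(labels, scores, positive_label: int = 1) -> float:
    """Area under the precision-recall curve (average-precision rule).

    Computed by the step-wise sum Σ (R_i - R_{i-1}) P_i over score
    thresholds, grouping tied scores.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValueError("labels/scores length mismatch")
    y = (labels == positive_label).astype(int)
    if y.min() == y.max():
        raise UndefinedMetric("AUPRC undefined with a single class")
    return float(average_precision_score(y, scores))


def site_variability(states: BinaryStateTable, catalog: SiteCatalog
                     ) -> np.ndarray:
    """Per-catalog-site binomial variance p(1-p) of observed states.

    NaN for sites observed in fewer than two cells (unstratifiable).
    """
    f = states.frame
    rows = catalog.lookup(f["chrom"].to_numpy(), f["pos"].to_numpy(),
                          f["strand"].to_numpy())
    n = np.zeros(len(catalog))
    s = np.zeros(len(catalog))
    np.add.at(n, rows, 1.0)
    np.add.at(s, rows, f["state"].to_numpy().astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = s / n
    var = p * (1.0 - p)
    var[n < 2] = np.nan
    return var


def downsample(states: BinaryStateTable, rate: float,
               seed: int = 0) -> BinaryStateTable:
    """Retain a uniform random subset of round(rate * n) observed entries.

    Each entry draws one uniform variate from the seeded stream over the
    canonically sorted entries, and the round(rate*n) smallest are kept —
    so for a fixed seed the retained sets are nested across rates and the
    retained count is exact.  rate=1 is the identity.
    """
    if not 0 < rate <= 1:
        raise ConfigError(f"rate must be in (0,1], got {rate}")
    table = states.sorted()
    n = len(table)
    if rate == 1:
        return table
    u = np.random.default_rng(seed).random(n)
    keep_n = round(rate * n)
    keep = np.sort(np.argsort(u, kind="stable")[:keep_n])
    return BinaryStateTable(table.frame.iloc[keep])


def downsample_sites(states: BinaryStateTable, rate: float,
                     seed: int = 0) -> BinaryStateTable:
    """Per-site variant: retain all entries of a random subset of sites."""
    if not 0 < rate <= 1:
        raise ConfigError(f"rate must be in (0,1], got {rate}")
    table = states.sorted()
    sites = table.frame[["chrom", "pos", "strand"]].drop_duplicates()
    sites = sites.sort_values(["chrom", "pos", "strand"])
    u = np.random.default_rng(seed).random(len(sites))
    keep_n = round(rate * len(sites))
    chosen = sites.iloc[np.sort(np.argsort(u, kind="stable")[:keep_n])]
    key = set(map(tuple, chosen.to_numpy()))
    mask = [tuple(r) in key for r in
            table.frame[["chrom", "pos", "strand"]].to_numpy()]
    return BinaryStateTable(table.frame[np.asarray(mask, dtype=bool)])


def _neighbor_index_table(catalog: SiteCatalog, n_side: int) -> np.ndarray:
    """(n_sites, 2*n_side) catalog rows of each site's scoring neighbors;
    -1 where a chromosome has too few CpGs."""
    from .encoding import neighbor_indices
    out = np.full((len(catalog), 2 * n_side), -1, dtype=np.int64)
    for i in range(len(catalog)):
        out[i] = neighbor_indices(catalog, i, 2 * n_side)
    return out


def quality_score(pred: PredictionMatrix, cell_id: str, site_row: int,
                  n_side: int = 5) -> float:
    """Mean |p(target) - p(neighbor)| over the site's 2*n_side nearest
    catalog CpGs within the same cell; NaN when no neighbor exists."""
    from .encoding import neighbor_indices
    i = pred.cells.index(cell_id)
    nbrs = neighbor_indices(pred.catalog, site_row, 2 * n_side)
    nbrs = nbrs[nbrs >= 0]
    if len(nbrs) == 0:
        warnings.warn(f"site row {site_row}: no scoreable neighbor")
        return float("nan")
    return float(np.mean(np.abs(pred.probs[i, site_row] - pred.probs[i, nbrs])))


def quality_scores(pred: PredictionMatrix, n_side: int = 5,
                   chunk: int = 512) -> np.ndarray:
    """(n_cells, n_sites) quality scores for every entry."""
    table = _neighbor_index_table(pred.catalog, n_side)
    n_cells, n_sites = pred.probs.shape
    out = np.full((n_cells, n_sites), np.nan)
    for start in range(0, n_sites, chunk):
        stop = min(start + chunk, n_sites)
        nbrs = table[start:stop]  # (S, 2m)
        valid = nbrs >= 0
        safe = np.where(valid, nbrs, 0)
        pv = pred.probs[:, safe]  # (C, S, 2m)
        diff = np.abs(pred.probs[:, start:stop, None] - pv)
        diff = np.where(valid[None], diff, np.nan)
        counts = valid.sum(axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            out[:, start:stop] = np.nanmean(diff, axis=2)
        if (counts == 0).any():
            warnings.warn("sites with no scoreable neighbor left unscored")
    return out


def filter_by_score(pred: PredictionMatrix, scores: np.ndarray,
                    threshold: float) -> PredictionMatrix:
    """Retain entries with score strictly below the threshold.

    Entries with undefined (NaN) scores are retained with a warning, since
    the score offers no evidence against them.
    """
    if not 0 <= threshold <= 1:
        raise ConfigError(f"threshold must be in [0,1], got {threshold}")
    undefined = ~np.isfinite(scores)
    if undefined.any():
        warnings.warn(f"{int(undefined.sum())} entries have undefined "
                      "quality scores; retained unfiltered")
    keep = (scores < threshold) | undefined
    return pred.with_retained(pred.retained & keep)


@dataclass
class EvalReport:
    """AUPRC overall and per stratum; NaN marks undefined (one-class) strata."""

    overall_auprc: float
    n_entries: int
    by_variability_decile: pd.DataFrame
    by_annotation: pd.DataFrame
    by_score_threshold: pd.DataFrame

    def to_json(self, path=None):
        payload = {
            "overall_auprc": self.overall_auprc,
            "n_entries": self.n_entries,
            "by_variability_decile": self.by_variability_decile.to_dict("records"),
            "by_annotation": self.by_annotation.to_dict("records"),
            "by_score_threshold": self.by_score_threshold.to_dict("records"),
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def read_bed_strata(path) -> pd.DataFrame:
    """BED (0-based half-open); column 4, when present, names the stratum."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#")
    bed = bed.iloc[:, :4] if bed.shape[1] >= 4 else bed.iloc[:, :3]
    bed.columns = (["chrom", "start", "end", "name"][:bed.shape[1]])
    if "name" not in bed.columns:
        bed["name"] = "region"
    return bed


def _annotate_sites(catalog: SiteCatalog, bed: pd.DataFrame) -> dict:
    """stratum name -> boolean site mask (0-based site position in
    [start, end))."""
    pos0 = catalog.pos - 1
    masks = {}
    for name, group in bed.groupby("name"):
        mask = np.zeros(len(catalog), dtype=bool)
        for chrom, sub in group.groupby("chrom"):
            if chrom not in catalog.chrom_ranges:
                continue
            a, b = catalog.chrom_ranges[chrom]
            p = pos0[a:b]
            for start, end in sub[["start", "end"]].itertuples(index=False):
                lo = np.searchsorted(p, start, side="left")
                hi = np.searchsorted(p, end, side="left")
                mask[a + lo:a + hi] = True
        masks[str(name)] = mask
    return masks


def _safe_auprc(labels, scores) -> float:
    try:
        return auprc(labels, scores)
    except UndefinedMetric:
        return float("nan")


def evaluate(pred: PredictionMatrix, held_out: BinaryStateTable,
             strata_bed: pd.DataFrame | None = None,
             thresholds: tuple = (), n_side: int = 5,
             scores: np.ndarray | None = None) -> EvalReport:
    """Score predictions against held-out binary states.

    Entries are (cell, site) pairs present in ``held_out``; predictions are
    read from the matrix at those entries.  Variability deciles are formed
    over held-out sites observed in >= 2 cells.  ``strata_bed`` adds
    per-annotation AUPRC; ``thresholds`` adds AUPRC after quality-score
    filtering at each threshold.
    """
    cells = pred.cells
    catalog = pred.catalog
    state_mat, observed = held_out.dense(cells, catalog)
    rows, cols = np.nonzero(observed)
    labels = state_mat[rows, cols].astype(int)
    probs = pred.probs[rows, cols]
    base_keep = pred.retained[rows, cols]
    overall = _safe_auprc(labels[base_keep], probs[base_keep])

    # variability deciles over evaluable sites
    var = site_variability(held_out, catalog)
    site_ok = np.isfinite(var)
    dec_rows = []
    if site_ok.sum() >= 10:
        edges = np.quantile(var[site_ok], np.linspace(0, 1, 11))
        edges[0], edges[-1] = -np.inf, np.inf
        decile_of_site = np.full(len(catalog), -1)
        decile_of_site[site_ok] = (
            np.clip(np.searchsorted(edges, var[site_ok], side="right") - 1,
                    0, 9))
        for d in range(10):
            sel = (decile_of_site[cols] == d) & base_keep
            dec_rows.append({
                "decile": d, "n_entries": int(sel.sum()),
                "auprc": (_safe_auprc(labels[sel], probs[sel])
                          if sel.any() else float("nan")),
            })
    by_decile = pd.DataFrame(dec_rows,
                             columns=["decile", "n_entries", "auprc"])

    ann_rows = []
    if strata_bed is not None:
        for name, mask in _annotate_sites(catalog, strata_bed).items():
            sel = mask[cols] & base_keep
            ann_rows.append({
                "annotation": name, "n_entries": int(sel.sum()),
                "auprc": (_safe_auprc(labels[sel], probs[sel])
                          if sel.any() else float("nan")),
            })
    by_ann = pd.DataFrame(ann_rows, columns=["annotation", "n_entries", "auprc"])

    thr_rows = []
    if thresholds:
        if scores is None:
            scores = quality_scores(pred, n_side=n_side)
        entry_scores = scores[rows, cols]
        for t in thresholds:
            keep = base_keep & ((entry_scores < t) | ~np.isfinite(entry_scores))
            thr_rows.append({
                "threshold": float(t), "n_entries": int(keep.sum()),
                "auprc": (_safe_auprc(labels[keep], probs[keep])
                          if keep.any() else float("nan")),
            })
    by_thr = pd.DataFrame(thr_rows, columns=["threshold", "n_entries", "auprc"])

    return EvalReport(overall, int(base_keep.sum()), by_decile, by_ann, by_thr)
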