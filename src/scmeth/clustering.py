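"""Cell clustering and cluster-level methylation profiles.

Cells are partitioned by their methylation levels in non-overlapping
genomic bins (100 kb in the full-scale setting): PCA on the cell x bin
level matrix followed by k-means with a fixed seed.  Externally supplied
labels are accepted anywhere a ClusterAssignment is, so pre-assigned cell
types can stand in for the inferred partition.

The per-cluster methylation level of a site is the read-weighted mean:
summed methylated reads over summed total reads across member cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .io import (BinaryStateTable, ConfigError, MethylationCallTable,
                 SiteCatalog, _chrom_sort_key)

logger = logging.getLogger(__name__)


@dataclass
class BinMethMatrix:
    """Cell x bin methylation levels with per-bin read coverage.

    ``values[i, j]`` is Σmc/Σcov over the cell's calls in the bin, NaN when
    coverage is zero.  Bins are [start, start + bin_size) half-open and tile
    each chromosome; the terminal partial bin is retained.
    """

    cells: list
    bins: pd.DataFrame  # columns chrom, start, end (0-based half-open)
    values: np.ndarray  # (n_cells, n_bins) float, NaN where no coverage
    coverage: np.ndarray  # (n_cells, n_bins) total reads (or site count)

    def __post_init__(self):
        assert self.values.shape == (len(self.cells), len(self.bins))


@dataclass
class ClusterAssignment:
    """cell_id -> cluster label in {1..n_clusters}."""

    labels: Mapping[str, int]

    def __post_init__(self):
        self.labels = dict(self.labels)
        if not self.labels:
            raise ConfigError("empty cluster assignment")

    @property
    def cells(self) -> list:
        return sorted(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    def vector(self, cells: Sequence[str]) -> np.ndarray:
        return np.asarray([self.labels[c] for c in cells], dtype=np.int64)

    def zero_based(self, cells: Sequence[str]) -> np.ndarray:
        """Labels remapped to 0..n_clusters-1 in sorted label order."""
        uniq = sorted(set(self.labels.values()))
        remap = {lab: i for i, lab in enumerate(uniq)}
        return np.asarray([remap[self.labels[c]] for c in cells], dtype=np.int64)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"cell": self.cells,
                      "cluster": [self.labels[c] for c in self.cells]}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ClusterAssignment":
        f = pd.read_csv(path, sep="\t")
        return cls(dict(zip(f["cell"], f["cluster"].astype(int))))


class ClusterProfile:
    """Per (cluster, site) read aggregates on a shared site catalog."""

    def __init__(self, catalog: SiteCatalog, mc_sum: np.ndarray,
                 cov_sum: np.ndarray, cluster_labels: Sequence[int]):
        mc_sum = np.asarray(mc_sum, dtype=np.int64)
        cov_sum = np.asarray(cov_sum, dtype=np.int64)
        if mc_sum.shape != cov_sum.shape or mc_sum.shape[1] != len(catalog):
            raise ValueError("profile shape mismatch")
        if np.any(mc_sum > cov_sum) or np.any(mc_sum < 0):
            raise ValueError("mc_sum must lie in [0, cov_sum]")
        self.catalog = catalog
        self.mc_sum = mc_sum
        self.cov_sum = cov_sum
        self.cluster_labels = list(cluster_labels)

    @property
    def n_clusters(self) -> int:
        return self.mc_sum.shape[0]

    @property
    def levels(self) -> np.ndarray:
        """(n_clusters, n_sites) levels, NaN where the cluster has no reads."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.mc_sum / self.cov_sum
        out[self.cov_sum == 0] = np.nan
        return out

    def level(self, cluster_label: int, site_row: int) -> float:
        k = self.cluster_labels.index(cluster_label)
        cov = self.cov_sum[k, site_row]
        return float(self.mc_sum[k, site_row] / cov) if cov else float("nan")

    def global_levels(self) -> np.ndarray:
        mc = self.mc_sum.sum(axis=0)
        cov = self.cov_sum.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = mc / cov
        out[cov == 0] = np.nan
        return out

    @classmethod
    def from_tables(cls, tables: Iterable[MethylationCallTable],
                    assignment: ClusterAssignment, catalog: SiteCatalog,
                    context_filter: str = "CG") -> "ClusterProfile":
        labels = sorted(set(assignment.labels.values()))
        pos_of = {lab: i for i, lab in enumerate(labels)}
        mc = np.zeros((len(labels), len(catalog)), dtype=np.int64)
        cov = np.zeros_like(mc)
        for table in tables:
            if table.cell_id not in assignment.labels:
                raise ConfigError(f"cell {table.cell_id} has no cluster")
            k = pos_of[assignment.labels[table.cell_id]]
            f = table.frame
            f = f[f["context"].str.startswith(context_filter)]
            known = [(c, int(p), s) in catalog._index
                     for c, p, s in zip(f["chrom"], f["pos"], f["strand"])]
            f = f[np.asarray(known, dtype=bool)] if len(f) else f
            if not len(f):
                continue
            rows = catalog.lookup(f["chrom"].to_numpy(), f["pos"].to_numpy(),
                                  f["strand"].to_numpy())
            np.add.at(mc[k], rows, f["mc"].to_numpy())
            np.add.at(cov[k], rows, f["cov"].to_numpy())
        return cls(catalog, mc, cov, labels)

    @classmethod
    def from_states(cls, states: BinaryStateTable,
                    assignment: ClusterAssignment,
                    catalog: SiteCatalog) -> "ClusterProfile":
        """Profile from binary states, each entry counted as one read."""
        labels = sorted(set(assignment.labels.values()))
        pos_of = {lab: i for i, lab in enumerate(labels)}
        mc = np.zeros((len(labels), len(catalog)), dtype=np.int64)
        cov = np.zeros_like(mc)
        f = states.frame
        ks = np.fromiter((pos_of[assignment.labels[c]] for c in f["cell"]),
                         dtype=np.int64, count=len(f))
        rows = catalog.lookup(f["chrom"].to_numpy(), f["pos"].to_numpy(),
                              f["strand"].to_numpy())
        np.add.at(mc, (ks, rows), f["state"].to_numpy().astype(np.int64))
        np.add.at(cov, (ks, rows), 1)
        return cls(catalog, mc, cov, labels)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _tile_bins(chrom_lengths: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    if bin_size <= 0:
        raise ConfigError("bin_size must be positive")
    rows = []
    for chrom in sorted(chrom_lengths, key=_chrom_sort_key):
        length = chrom_lengths[chrom]
        for start in range(0, length, bin_size):
            rows.append((chrom, start, min(start + bin_size, length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _chrom_lengths(genome) -> Mapping[str, int]:
    first = next(iter(genome.values()), None)
    if isinstance(first, str):
        return {c: len(s) for c, s in genome.items()}
    return genome


def compute_bin_matrix(tables: Iterable[MethylationCallTable], genome,
                       bin_size: int = 100_000,
                       context_filter: str = "CG") -> BinMethMatrix:
    """Cell x bin read-weighted methylation levels.

    ``genome`` may be a GenomeSequence or a {chrom: length} mapping.
    """
    lengths = _chrom_lengths(genome)
    bins = _tile_bins(lengths, bin_size)
    offsets = {}
    for chrom in lengths:
        first = bins.index[bins["chrom"] == chrom]
        offsets[chrom] = int(first[0]) if len(first) else -1
    tables = list(tables)
    cells = [t.cell_id for t in tables]
    mc = np.zeros((len(cells), len(bins)), dtype=np.float64)
    cov = np.zeros_like(mc)
    for i, table in enumerate(tables):
        f = table.frame
        f = f[f["context"].str.startswith(context_filter)]
        f = f[f["chrom"].isin(lengths)]
        if not len(f):
            continue
        bin_idx = np.fromiter(
            (offsets[c] + (p - 1) // bin_size
             for c, p in zip(f["chrom"], f["pos"])),
            dtype=np.int64, count=len(f))
        np.add.at(mc[i], bin_idx, f["mc"].to_numpy())
        np.add.at(cov[i], bin_idx, f["cov"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        values = mc / cov
    values[cov == 0] = np.nan
    return BinMethMatrix(cells, bins, values, cov)


def bin_matrix_from_predictions(pred, genome, bin_size: int = 100_000
                                ) -> BinMethMatrix:
    """Bin levels from imputed probabilities (mean probability per bin).

    Entries removed by quality filtering are excluded from the mean.
    """
    lengths = _chrom_lengths(genome)
    bins = _tile_bins(lengths, bin_size)
    offsets = {}
    for chrom in lengths:
        first = bins.index[bins["chrom"] == chrom]
        offsets[chrom] = int(first[0]) if len(first) else -1
    cat = pred.catalog
    bin_idx = np.fromiter((offsets[c] + (p - 1) // bin_size
                           for c, p in zip(cat.chrom, cat.pos)),
                          dtype=np.int64, count=len(cat))
    n_cells = len(pred.cells)
    total = np.zeros((n_cells, len(bins)))
    count = np.zeros_like(total)
    probs = np.where(pred.retained, pred.probs, 0.0)
    for i in range(n_cells):
        np.add.at(total[i], bin_idx, probs[i])
        np.add.at(count[i], bin_idx, pred.retained[i].astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        values = total / count
    values[count == 0] = np.nan
    return BinMethMatrix(list(pred.cells), bins, values, count)


def cluster_cells(matrix: BinMethMatrix, n_clusters: int, seed: int = 0,
                  n_components: int = 20) -> ClusterAssignment:
    """PCA + k-means on bin levels; deterministic given seed.

    Missing bin values are imputed with the per-bin mean across cells for
    the clustering only (profiles never see imputed values).
    """
    n_cells = len(matrix.cells)
    if n_clusters > n_cells:
        raise ConfigError(f"n_clusters={n_clusters} exceeds {n_cells} cells")
    x = matrix.values.copy()
    col_mean = np.nanmean(np.where(np.isfinite(x), x, np.nan), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.5)
    missing = ~np.isfinite(x)
    x[missing] = np.broadcast_to(col_mean, x.shape)[missing]
    k = min(n_components, n_cells - 1, x.shape[1])
    if k >= 1:
        x = PCA(n_components=k, random_state=seed).fit_transform(x)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(x)
    return ClusterAssignment({c: int(l) + 1 for c, l in zip(matrix.cells, labels)})


def build_cluster_profiles(tables, assignment: ClusterAssignment,
                           catalog: SiteCatalog,
                           context_filter: str = "CG") -> ClusterProfile:
    return ClusterProfile.from_tables(tables, assignment, catalog,
                                      context_filter)


def adjusted_rand_index(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Permutation-model ARI between two partitions of the same cells."""
    if set(a.labels) != set(b.labels):
        raise ConfigError("cluster assignments cover different cell sets")
    cells = a.cells
    return float(adjusted_rand_score(a.vector(cells), b.vector(cells)))
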