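"""Model input construction.

Each target CpG becomes one example with two modalities:

* a one-hot DNA window of L bases (L x 4, rows 5'->3', columns A,C,G,T)
  centered on the target cytosine; N bases and out-of-chromosome padding
  are all-zero rows, and minus-strand targets are encoded on the reverse
  complement so the CG motif always reads 5'->3';
* a K x N matrix of cluster-level methylation levels at the K catalog CpGs
  nearest the target (K/2 upstream, K/2 downstream, borrowing across the
  target when a chromosome end leaves one side short), the target itself
  excluded.  Undefined cluster levels carry the sentinel -1, outside the
  valid [0, 1] range.

The label vector holds the observed binary states over a fixed cell
ordering, with a boolean observed mask; only masked-true entries ever
contribute to the training loss.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .clustering import ClusterProfile
from .io import BinaryStateTable, GenomeSequence, SiteCatalog

SENTINEL = -1.0

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


class GenomeEncoder:
    """Caches integer-coded chromosomes for fast window extraction."""

    def __init__(self, genome: GenomeSequence):
        self.codes = {}
        for name, seq in genome.items():
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            code = np.full(arr.shape, -1, dtype=np.int8)
            for base, value in _BASE_CODE.items():
                code[arr == ord(base)] = value
            self.codes[name] = code

    def window(self, chrom: str, pos: int, strand: str, length: int,
               rc_minus: bool = True) -> np.ndarray:
        """One-hot window of ``length`` bases with the target C at index
        length // 2; ``pos`` is 1-based."""
        if length % 2:
            raise ValueError("window length must be even")
        if chrom not in self.codes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        code = self.codes[chrom]
        center = pos - 1
        half = length // 2
        rc = strand == "-" and rc_minus
        # minus-strand windows shift by +1 so the complementary C sits at
        # index length//2 after reverse complementation
        start = center - half + 1 if rc else center - half
        idx = np.arange(start, start + length)
        valid = (idx >= 0) & (idx < len(code))
        vals = np.full(length, -1, dtype=np.int8)
        vals[valid] = code[idx[valid]]
        if rc:
            vals = vals[::-1]
            swap = vals >= 0
            vals = vals.copy()
            vals[swap] = _COMPLEMENT[vals[swap]]
        onehot = np.zeros((length, 4), dtype=np.float64)
        rows = np.flatnonzero(vals >= 0)
        onehot[rows, vals[rows]] = 1.0
        return onehot


def encode_dna_window(genome: GenomeSequence, chrom: str, pos: int,
                      strand: str = "+", length: int = 2000,
                      rc_minus: bool = True) -> np.ndarray:
    return GenomeEncoder({chrom: genome[chrom]}).window(
        chrom, pos, strand, length, rc_minus)


def neighbor_indices(catalog: SiteCatalog, site_row: int, k: int) -> np.ndarray:
    """Catalog rows of the K neighbors of a target site.

    K/2 nearest upstream and K/2 nearest downstream catalog CpGs on the
    target's chromosome, borrowing from the other side near chromosome
    ends; -1 marks padding when fewer than K other CpGs exist.
    Rows come back in increasing genomic position.
    """
    if k % 2:
        raise ValueError("neighbor count K must be even")
    chrom = catalog.chrom[site_row]
    a, b = catalog.chrom_ranges[chrom]
    half = k // 2
    n_up = site_row - a
    n_down = b - site_row - 1
    take_up = min(half + max(0, half - n_down), n_up)
    take_down = min(half + max(0, half - n_up), n_down)
    rows = np.concatenate([
        np.arange(site_row - take_up, site_row),
        np.arange(site_row + 1, site_row + 1 + take_down),
    ])
    if len(rows) < k:
        rows = np.concatenate([rows, np.full(k - len(rows), -1, dtype=np.int64)])
    return rows


def build_neighbor_tensor(profile: ClusterProfile, site_row: int, k: int):
    """(K x n_clusters levels matrix, target_row_index).

    The target-row index is the boundary between upstream and downstream
    neighbors (K/2) in the K-window coordinate frame.
    """
    rows = neighbor_indices(profile.catalog, site_row, k)
    levels = profile.levels  # (n_clusters, n_sites)
    out = np.full((k, profile.n_clusters), SENTINEL, dtype=np.float64)
    valid = rows >= 0
    vals = levels[:, rows[valid]].T
    vals = np.where(np.isfinite(vals), vals, SENTINEL)
    out[valid] = vals
    return out, k // 2


@dataclass
class ExampleSet:
    """A batch-ready collection of examples over a fixed cell ordering.

    dna: (n, L, 4); neighbors: (n, K, N); labels/mask: (n, n_cells).
    Examples are ordered by catalog row, i.e. by (chrom, pos).
    """

    site_rows: np.ndarray
    catalog: SiteCatalog
    cells: list
    dna: np.ndarray
    neighbors: np.ndarray
    target_row_index: int
    labels: np.ndarray
    mask: np.ndarray

    def __len__(self) -> int:
        return len(self.site_rows)

    def batches(self, batch_size: int, rng: np.random.Generator | None = None):
        order = np.arange(len(self))
        if rng is not None:
            rng.shuffle(order)
        for start in range(0, len(order), batch_size):
            sel = order[start:start + batch_size]
            yield (self.dna[sel], self.neighbors[sel],
                   self.labels[sel], self.mask[sel])


def make_examples(states: BinaryStateTable, profile: ClusterProfile,
                  genome: GenomeSequence, cells: Sequence[str],
                  k: int = 100, length: int = 2000,
                  site_rows: np.ndarray | None = None,
                  require_observed: bool = True,
                  neighbor_catalog_rows: np.ndarray | None = None,
                  rc_minus: bool = True) -> ExampleSet:
    """Build the example set for the given catalog rows.

    With ``require_observed`` (training/evaluation), sites with no observed
    cell are dropped.  ``site_rows`` defaults to every catalog row.
    The neighbor window is drawn from the profile's catalog, optionally
    restricted to ``neighbor_catalog_rows`` (e.g. dataset-covered sites).
    """
    catalog = profile.catalog
    cells = list(cells)
    state_mat, observed = states.dense(cells, catalog)
    if site_rows is None:
        site_rows = np.arange(len(catalog))
    site_rows = np.sort(np.asarray(site_rows, dtype=np.int64))
    if require_observed:
        site_rows = site_rows[observed[:, site_rows].any(axis=0)]

    if neighbor_catalog_rows is not None:
        sub_rows = np.sort(np.asarray(neighbor_catalog_rows, dtype=np.int64))
        sub_cat = SiteCatalog(catalog.chrom[sub_rows], catalog.pos[sub_rows],
                              catalog.strand[sub_rows])
        sub_profile = ClusterProfile(sub_cat, profile.mc_sum[:, sub_rows],
                                     profile.cov_sum[:, sub_rows],
                                     profile.cluster_labels)
    else:
        sub_rows, sub_cat, sub_profile = None, catalog, profile

    encoder = GenomeEncoder(genome)
    n = len(site_rows)
    dna = np.zeros((n, length, 4), dtype=np.float64)
    neighbors = np.zeros((n, k, profile.n_clusters), dtype=np.float64)
    tri = k // 2
    levels = sub_profile.levels
    for i, row in enumerate(site_rows):
        chrom, pos, strand = catalog.site(row)
        dna[i] = encoder.window(chrom, pos, strand, length, rc_minus)
        if sub_rows is not None:
            # position of the target within (or between rows of) the
            # restricted catalog; neighbor_indices needs an actual row, so
            # temporarily use the insertion point's flanks
            nb = _neighbors_around(sub_cat, chrom, pos, k)
        else:
            nb = neighbor_indices(sub_cat, row, k)
            nb = nb  # target excluded by construction
        block = np.full((k, profile.n_clusters), SENTINEL)
        valid = nb >= 0
        vals = levels[:, nb[valid]].T
        block[valid] = np.where(np.isfinite(vals), vals, SENTINEL)
        neighbors[i] = block
    return ExampleSet(site_rows, catalog, cells, dna, neighbors, tri,
                      state_mat[:, site_rows].T.astype(np.float64),
                      observed[:, site_rows].T)


def _neighbors_around(catalog: SiteCatalog, chrom: str, pos: int, k: int
                      ) -> np.ndarray:
    """K nearest catalog rows around an arbitrary genomic position,
    excluding an exact-match row (the target itself)."""
    if chrom not in catalog.chrom_ranges:
        return np.full(k, -1, dtype=np.int64)
    a, b = catalog.chrom_ranges[chrom]
    positions = catalog.pos[a:b]
    ins = int(np.searchsorted(positions, pos))
    exact = ins < len(positions) and positions[ins] == pos
    half = k // 2
    up = np.arange(max(0, ins - half - k), ins)
    down_start = ins + 1 if exact else ins
    down = np.arange(down_start, min(len(positions), down_start + half + k))
    n_up, n_down = len(up), len(down)
    take_up = min(half + max(0, half - n_down), n_up)
    take_down = min(half + max(0, half - n_up), n_down)
    rows = np.concatenate([up[n_up - take_up:], down[:take_down]]) + a
    if len(rows) < k:
        rows = np.concatenate([rows, np.full(k - len(rows), -1, dtype=np.int64)])
    return rows
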