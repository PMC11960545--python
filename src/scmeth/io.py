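"""Reading and writing single-cell methylome data.

The on-disk substrate is the ALLC convention used by methylpy-style
pipelines: one tab-separated row per cytosine with columns

    chrom  pos(1-based)  strand  context  mc  cov  [methylated-flag]

where ``mc`` is the number of reads supporting methylation and ``cov`` the
total number of reads covering the cytosine.  Files may be gzip-compressed;
an optional seventh column is accepted and ignored on read and emitted as
``1``/``0`` on write.

Coordinates are 1-based in files (the ALLC standard) and converted to
0-based half-open only inside window arithmetic, never here.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov"]

_NON_ACGT = re.compile(r"[^ACGT]")


class AllcParseError(ValueError):
    """A malformed ALLC record (bad counts, bad coordinate, duplicate site)."""


class ConfigError(ValueError):
    """An invalid configuration value (empty split list, bad threshold...)."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------


def _chrom_sort_key(name: str):
    """Natural ordering so chr2 < chr10 and s1 < s10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass
class MethylationCall:
    """One cytosine record: counts of methylated vs total reads."""

    chrom: str
    pos: int  # 1-based
    strand: str
    context: str
    mc: int
    cov: int

    def __post_init__(self):
        if self.pos < 1:
            raise AllcParseError(f"position must be >= 1, got {self.pos}")
        if self.cov < 1:
            raise AllcParseError(f"cov must be >= 1, got {self.cov}")
        if not 0 <= self.mc <= self.cov:
            raise AllcParseError(f"mc={self.mc} outside [0, cov={self.cov}]")


class MethylationCallTable:
    """All cytosine calls of one cell, unique per (chrom, pos, strand)."""

    def __init__(self, cell_id: str, frame: pd.DataFrame):
        self.cell_id = cell_id
        frame = frame.reset_index(drop=True)
        missing = [c for c in ALLC_COLUMNS if c not in frame.columns]
        if missing:
            raise AllcParseError(f"missing columns: {missing}")
        self.frame = frame[ALLC_COLUMNS].copy()
        self._validate()

    def _validate(self) -> None:
        f = self.frame
        bad = (f["mc"] > f["cov"]) | (f["cov"] < 1) | (f["mc"] < 0) | (f["pos"] < 1)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise AllcParseError(
                f"cell {self.cell_id}: invalid counts/position at record {i}: "
                f"{f.iloc[i].to_dict()}"
            )
        dup = f.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            i = int(np.flatnonzero(dup.to_numpy())[0])
            raise AllcParseError(
                f"cell {self.cell_id}: duplicate (chrom, pos, strand) at record {i}: "
                f"({f.iloc[i]['chrom']}, {f.iloc[i]['pos']}, {f.iloc[i]['strand']})"
            )

    def __len__(self) -> int:
        return len(self.frame)

    def sorted(self) -> "MethylationCallTable":
        key = self.frame["chrom"].map(_chrom_sort_key)
        order = self.frame.assign(_k=key).sort_values(["_k", "pos", "strand"]).index
        return MethylationCallTable(self.cell_id, self.frame.loc[order])

    def calls(self) -> Iterable[MethylationCall]:
        for row in self.frame.itertuples(index=False):
            yield MethylationCall(row.chrom, int(row.pos), row.strand, row.context,
                                  int(row.mc), int(row.cov))


@dataclass(frozen=True)
class ChromosomeSplit:
    """Disjoint chromosome lists routing sites to train / validation / test."""

    train: tuple
    val: tuple
    test: tuple

    def __post_init__(self):
        for name, lst in (("train", self.train), ("val", self.val), ("test", self.test)):
            if len(lst) == 0:
                raise ConfigError(f"{name} split list is empty")
        object.__setattr__(self, "train", tuple(self.train))
        object.__setattr__(self, "val", tuple(self.val))
        object.__setattr__(self, "test", tuple(self.test))
        all_ = list(self.train) + list(self.val) + list(self.test)
        if len(set(all_)) != len(all_):
            raise ConfigError("split lists overlap")

    @classmethod
    def default_human(cls) -> "ChromosomeSplit":
        return cls(train=tuple(f"chr{i}" for i in range(1, 21)),
                   val=("chr21",), test=("chr22",))


class SiteCatalog:
    """An ordered catalog of cytosine sites, sorted by (chrom, pos, strand).

    The catalog is the coordinate frame shared by cluster profiles,
    neighbor windows and prediction matrices: a site is addressed by its
    integer row in the catalog.
    """

    def __init__(self, chrom: np.ndarray, pos: np.ndarray, strand: np.ndarray):
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        strand = np.asarray(strand, dtype=object)
        keys = sorted(range(len(pos)),
                      key=lambda i: (_chrom_sort_key(chrom[i]), pos[i], strand[i]))
        keys = np.asarray(keys, dtype=np.int64)
        self.chrom = chrom[keys]
        self.pos = pos[keys]
        self.strand = strand[keys]
        self._index = {
            (c, int(p), s): i
            for i, (c, p, s) in enumerate(zip(self.chrom, self.pos, self.strand))
        }
        if len(self._index) != len(self.pos):
            raise AllcParseError("duplicate sites in catalog")
        # contiguous [start, stop) row ranges per chromosome
        self.chrom_ranges: dict = {}
        if len(self.chrom):
            bounds = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
            starts = np.concatenate([[0], bounds])
            stops = np.concatenate([bounds, [len(self.chrom)]])
            self.chrom_ranges = {self.chrom[a]: (int(a), int(b))
                                 for a, b in zip(starts, stops)}

    def __len__(self) -> int:
        return len(self.pos)

    def index_of(self, chrom: str, pos: int, strand: str = "+") -> int:
        return self._index[(chrom, int(pos), strand)]

    def lookup(self, chrom, pos, strand) -> np.ndarray:
        """Vectorized site -> row lookup; KeyError on unknown site."""
        return np.fromiter(
            (self._index[(c, int(p), s)] for c, p, s in zip(chrom, pos, strand)),
            dtype=np.int64, count=len(pos))

    def site(self, i: int):
        return (self.chrom[i], int(self.pos[i]), self.strand[i])

    @classmethod
    def from_genome(cls, genome: Mapping[str, str], context: str = "CG") -> "SiteCatalog":
        """Catalog every occurrence of ``context`` (plus-strand C positions)."""
        chroms, positions = [], []
        for name in sorted(genome, key=_chrom_sort_key):
            seq = genome[name]
            start = seq.find(context)
            while start != -1:
                chroms.append(name)
                positions.append(start + 1)  # 1-based C
                start = seq.find(context, start + 1)
        n = len(positions)
        return cls(np.array(chroms, dtype=object),
                   np.array(positions, dtype=np.int64),
                   np.array(["+"] * n, dtype=object))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SiteCatalog":
        sub = frame[["chrom", "pos", "strand"]].drop_duplicates()
        return cls(sub["chrom"].to_numpy(), sub["pos"].to_numpy(),
                   sub["strand"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "pos": self.pos,
                             "strand": self.strand})

    def subset_chroms(self, chroms: Sequence[str]) -> np.ndarray:
        """Row indices of sites lying on the listed chromosomes."""
        wanted = set(chroms)
        parts = [np.arange(a, b) for c, (a, b) in self.chrom_ranges.items()
                 if c in wanted]
        if not parts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(parts)


class BinaryStateTable:
    """Sparse (cell, site) -> {0, 1} methylation states.

    States come from the all-reads-agree rule: 1 when every read supports
    methylation, 0 when every read supports unmethylation; mixed-read sites
    are simply absent (they carry no binary label, not a missing value).
    """

    def __init__(self, frame: pd.DataFrame):
        cols = ["cell", "chrom", "pos", "strand", "state"]
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        frame = frame[cols].reset_index(drop=True)
        if not frame["state"].isin([0, 1]).all():
            raise ValueError("states must be 0 or 1")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def cells(self) -> list:
        return sorted(self.frame["cell"].unique())

    def sorted(self) -> "BinaryStateTable":
        key = self.frame["chrom"].map(_chrom_sort_key)
        order = (self.frame.assign(_k=key)
                 .sort_values(["cell", "_k", "pos", "strand"]).index)
        return BinaryStateTable(self.frame.loc[order])

    def subset_chroms(self, chroms: Sequence[str]) -> "BinaryStateTable":
        keep = self.frame["chrom"].isin(set(chroms))
        return BinaryStateTable(self.frame[keep])

    def dense(self, cells: Sequence[str], catalog: SiteCatalog):
        """(states uint8, observed bool) matrices of shape (n_cells, n_sites).

        Entries absent from the table have observed=False and state=0.
        """
        cell_idx = {c: i for i, c in enumerate(cells)}
        states = np.zeros((len(cells), len(catalog)), dtype=np.uint8)
        observed = np.zeros_like(states, dtype=bool)
        f = self.frame
        rows = np.fromiter((cell_idx[c] for c in f["cell"]), dtype=np.int64,
                           count=len(f))
        cols = catalog.lookup(f["chrom"].to_numpy(), f["pos"].to_numpy(),
                              f["strand"].to_numpy())
        states[rows, cols] = f["state"].to_numpy()
        observed[rows, cols] = True
        return states, observed

    def to_tsv(self, path) -> None:
        self.sorted().frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinaryStateTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_tables(cls, tables: Iterable[MethylationCallTable],
                    context_filter: str = "CG") -> "BinaryStateTable":
        parts = [call_binary_states(t, context_filter).frame for t in tables]
        if not parts:
            return cls(pd.DataFrame(columns=["cell", "chrom", "pos", "strand",
                                             "state"]))
        return cls(pd.concat(parts, ignore_index=True))


GenomeSequence = dict  # chromosome name -> upper-case sequence over {A,C,G,T,N}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def read_allc(path, cell_id: str) -> MethylationCallTable:
    """Read one cell's ALLC table (gzip transparent, 6 or 7 columns)."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=range(6))
    if raw.shape[1] < 6:
        raise AllcParseError(f"{path}: expected >= 6 tab-separated columns, "
                             f"got {raw.shape[1]}")
    raw = raw.iloc[:, :6]
    raw.columns = ALLC_COLUMNS
    for col in ("pos", "mc", "cov"):
        num = pd.to_numeric(raw[col], errors="coerce")
        bad = num.isna() | (num != num.round())
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise AllcParseError(f"{path}:{line}: non-integer value "
                                 f"{raw[col].iloc[line - 1]!r} in column {col}")
        raw[col] = num.astype(np.int64)
    bad = (raw["mc"] > raw["cov"]) | (raw["cov"] < 1) | (raw["mc"] < 0) | (raw["pos"] < 1)
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise AllcParseError(f"{path}:{line}: invalid counts/position "
                             f"{tuple(raw.iloc[line - 1][['pos', 'mc', 'cov']])}")
    dup = raw.duplicated(subset=["chrom", "pos", "strand"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 1
        raise AllcParseError(f"{path}:{line}: duplicate (chrom, pos, strand)")
    return MethylationCallTable(cell_id, raw)


def write_allc(table: MethylationCallTable, path) -> None:
    """Write an ALLC table with the 7-column dialect (flag = 1 iff mc > 0)."""
    f = table.sorted().frame.copy()
    f["flag"] = (f["mc"] > 0).astype(int)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        f.to_csv(fh, sep="\t", header=False, index=False)


def call_binary_states(table: MethylationCallTable,
                       context_filter: str = "CG") -> BinaryStateTable:
    """Apply the all-reads-agree rule to one cell's calls.

    A site is 1 when mc == cov, 0 when mc == 0; sites whose reads support
    both states (0 < mc < cov) are dropped.  ``context_filter`` is a prefix
    match on the context column ("CG" keeps CGA/CGC/CGN...).
    """
    f = table.frame
    keep = f["context"].str.startswith(context_filter)
    f = f[keep]
    concordant = (f["mc"] == 0) | (f["mc"] == f["cov"])
    f = f[concordant]
    out = pd.DataFrame({
        "cell": table.cell_id,
        "chrom": f["chrom"].to_numpy(),
        "pos": f["pos"].to_numpy(),
        "strand": f["strand"].to_numpy(),
        "state": (f["mc"] > 0).astype(np.uint8).to_numpy(),
    })
    return BinaryStateTable(out)


def split_sites(catalog: SiteCatalog, split: ChromosomeSplit):
    """Route catalog rows into (train, val, test) index arrays.

    Sites on chromosomes absent from every split list are dropped with a
    logged count.
    """
    listed = set(split.train) | set(split.val) | set(split.test)
    present = set(catalog.chrom_ranges)
    dropped = sum(b - a for c, (a, b) in catalog.chrom_ranges.items()
                  if c not in listed)
    if dropped:
        logger.warning("split_sites: %d sites on unlisted chromosomes dropped",
                       dropped)
    if not (present & listed):
        logger.warning("split_sites: no catalog chromosome matches the split")
    return (catalog.subset_chroms(split.train),
            catalog.subset_chroms(split.val),
            catalog.subset_chroms(split.test))


def write_imputed_allc(pred, threshold: float, out_dir,
                       context: str = "CGN") -> list:
    """Export a PredictionMatrix as one depth-1 ALLC file per cell.

    Each imputed site is emitted as covered by exactly one read: mc=1 cov=1
    when probability >= threshold (ties go methylated), else mc=0 cov=1.
    Entries dropped by quality filtering (pred.retained False) are omitted.
    Returns the written paths, ordered like pred.cells.
    """
    if not 0 < threshold < 1:
        raise ConfigError(f"threshold must be in (0,1), got {threshold}")
    if np.any(pred.probs < 0) or np.any(pred.probs > 1):
        raise ValueError("probabilities outside [0,1]")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cat = pred.catalog
    paths = []
    for i, cell in enumerate(pred.cells):
        keep = pred.retained[i]
        mc = (pred.probs[i, keep] >= threshold).astype(int)
        frame = pd.DataFrame({
            "chrom": cat.chrom[keep], "pos": cat.pos[keep],
            "strand": cat.strand[keep], "context": context,
            "mc": mc, "cov": 1,
        })
        path = out_dir / f"{cell}.allc.tsv"
        write_allc(MethylationCallTable(cell, frame), path)
        paths.append(path)
    return paths


def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file into {name: upper-case ACGTN string}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genome: GenomeSequence = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in genome:
                raise AllcParseError(f"duplicate FASTA record {rec.id!r}")
            seq = _NON_ACGT.sub("N", str(rec.seq).upper())
            if not seq:
                raise AllcParseError(f"empty FASTA record {rec.id!r}")
            genome[rec.id] = seq
    if not genome:
        raise AllcParseError(f"{path}: no FASTA records")
    return genome


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome, key=_chrom_sort_key):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def merge_symmetric_strands(table: MethylationCallTable,
                            genome: GenomeSequence) -> MethylationCallTable:
    """Sum the two strands of each symmetric CpG onto the plus-strand C.

    Optional preprocessing; off by default since the raw per-strand records
    are themselves a valid substrate.
    """
    f = table.frame.copy()
    minus = f["strand"] == "-"
    # a minus-strand call at pos p pairs with the plus-strand C at p-1 when
    # the reference has CG there
    shifted = f.loc[minus, "pos"] - 1
    ok = []
    for chrom, p in zip(f.loc[minus, "chrom"], shifted):
        seq = genome.get(chrom, "")
        ok.append(1 <= p <= len(seq) - 1 and seq[p - 1:p + 1] == "CG")
    ok = np.asarray(ok, dtype=bool)
    idx = f.index[minus][ok]
    f.loc[idx, "pos"] = f.loc[idx, "pos"] - 1
    f.loc[idx, "strand"] = "+"
    agg = (f.groupby(["chrom", "pos", "strand"], as_index=False)
           .agg({"context": "first", "mc": "sum", "cov": "sum"}))
    return MethylationCallTable(table.cell_id, agg)
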