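"""Synthetic single-cell methylome generator with known ground truth.

The generator emulates the structure of single-nucleus bisulfite datasets:

* a random genome with CpG dinucleotides planted at a controlled density
  and short sequence motifs planted at recorded positions;
* a cluster-structured methylome: per 20 kb block, a shared baseline logit
  drawn from a mostly-methylated regime, plus cluster-specific
  hypomethylated blocks (synthetic DMRs) and motif effects
  (sequence-dependent hypomethylation) added on the logit scale;
* sparse sampling: each cell carries its cluster's per-site Bernoulli
  methylation state, each (cell, site) entry is observed with the coverage
  rate (~5% of CpGs per cell in the real technologies), and read depths
  are drawn with all reads concordant with the drawn state, so binary
  state calling recovers the simulation exactly (an optional discordance
  rate plants mixed-read records to exercise the exclusion rule).

Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (BinaryStateTable, ChromosomeSplit, GenomeSequence,
                 MethylationCallTable, SiteCatalog, write_allc, write_fasta)

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    The default scale — 200 cells, 4 clusters, five 200 kb chromosomes at
    CpG density 0.004 (~4,000 CpGs), coverage 0.10 — trains the scaled
    model in minutes on one CPU while keeping per-site cluster coverage
    realistically sparse.
    """

    n_cells: int = 200
    n_clusters: int = 4
    chrom_lengths: Mapping[str, int] = field(default_factory=lambda: {
        f"s{i}": 200_000 for i in range(1, 6)})
    split: ChromosomeSplit = field(default_factory=lambda: ChromosomeSplit(
        train=("s1", "s2", "s3"), val=("s4",), test=("s5",)))
    cpg_density: float = 0.004
    # hypomethylation motifs with distinct effect sizes on the logit scale
    motifs: Mapping[str, float] = field(default_factory=lambda: {
        "TACGCAAT": -4.0, "CCTCGAGG": -1.5})
    motifs_per_chrom: int = 40  # instances of each motif per chromosome
    baseline_block: int = 20_000
    baseline_logit_range: tuple = (0.5, 2.0)  # mostly-methylated genome
    n_dmr_per_cluster: int = 10
    dmr_width: int = 15_000
    dmr_shift: float = -3.5  # cluster-specific hypomethylation
    coverage: float = 0.10
    read_depth_lambda: float = 0.3  # depth = 1 + Poisson(lambda)
    discordance_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage must be in (0,1]")
        if not 0 < self.cpg_density < 0.5:
            raise ValueError("cpg_density must be in (0, 0.5)")
        for motif in self.motifs:
            if set(motif) - set("ACGT"):
                raise ValueError(f"motif {motif!r} contains non-ACGT bases")
        if isinstance(self.split, dict):
            self.split = ChromosomeSplit(**self.split)


@dataclass
class GroundTruth:
    """Planted structure: cluster per cell, probability per (cluster, site),
    and motif-affected site flags."""

    cell_clusters: np.ndarray  # (n_cells,) labels in 1..n_clusters
    probs: np.ndarray  # (n_clusters, n_sites)
    motif_affected: np.ndarray  # (n_sites,) bool
    motif_effect: np.ndarray  # (n_sites,) summed logit effect
    baseline_logit: np.ndarray  # (n_sites,)
    dmr_shift: np.ndarray  # (n_clusters, n_sites)
    dmr_blocks: pd.DataFrame  # chrom, start, end, cluster, shift


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: GenomeSequence
    catalog: SiteCatalog
    truth: GroundTruth
    tables: list  # MethylationCallTable per cell
    states: BinaryStateTable

    @property
    def cells(self) -> list:
        return [t.cell_id for t in self.tables]

    def planted_assignment(self):
        from .clustering import ClusterAssignment
        return ClusterAssignment({c: int(k) for c, k in
                                  zip(self.cells, self.truth.cell_clusters)})

    def write(self, out_dir) -> dict:
        """Emit FASTA, per-cell ALLC, truth tables and config echo."""
        import yaml
        out = Path(out_dir)
        (out / "allc").mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, out / "genome.fa")
        for table in self.tables:
            write_allc(table, out / "allc" / f"{table.cell_id}.allc.tsv")
        self.states.to_tsv(out / "states.tsv")
        pd.DataFrame({"cell": self.cells,
                      "cluster": self.truth.cell_clusters}
                     ).to_csv(out / "true_clusters.tsv", sep="\t", index=False)
        truth_sites = self.catalog.to_frame()
        truth_sites["motif_affected"] = self.truth.motif_affected
        truth_sites["baseline_logit"] = self.truth.baseline_logit
        for i in range(self.config.n_clusters):
            truth_sites[f"prob_cluster{i + 1}"] = self.truth.probs[i]
        truth_sites.to_csv(out / "true_site_probs.tsv", sep="\t", index=False)
        cfg = asdict(self.config)
        cfg["chrom_lengths"] = dict(cfg["chrom_lengths"])
        cfg["split"] = {k: list(v) for k, v in
                        zip(("train", "val", "test"),
                            (self.config.split.train, self.config.split.val,
                             self.config.split.test))}
        cfg["motifs"] = dict(cfg["motifs"])
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        return {"fasta": str(out / "genome.fa"), "allc_dir": str(out / "allc"),
                "states": str(out / "states.tsv"),
                "true_clusters": str(out / "true_clusters.tsv")}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_genome(config: SyntheticConfig,
                    rng: np.random.Generator | None = None):
    """Random genome with planted CpGs and motif instances.

    Returns (genome, catalog, motif_instances frame).  The background
    sequence never contains CG by construction, so the catalog is the
    planted CpGs plus those inside motif instances.
    """
    rng = rng or np.random.default_rng(config.seed)
    genome: GenomeSequence = {}
    motif_rows = []
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        # background with CG suppressed: after a C, never draw G
        seq = rng.choice(_BASES, size=length)
        prev_c = np.concatenate([[False], seq[:-1] == "C"])
        bad = prev_c & (seq == "G")
        while bad.any():
            seq[bad] = rng.choice(np.array(list("ACT")), size=int(bad.sum()))
            prev_c = np.concatenate([[False], seq[:-1] == "C"])
            bad = prev_c & (seq == "G")
        # plant CpGs
        cand = np.flatnonzero(rng.random(length - 1) < config.cpg_density)
        keep = []
        last = -2
        for p in cand:
            if p - last >= 2:
                keep.append(p)
                last = p
        for p in keep:
            seq[p] = "C"
            seq[p + 1] = "G"
        # plant motifs at spaced random positions
        occupied = []
        for motif, _effect in sorted(config.motifs.items()):
            m = np.array(list(motif))
            starts = np.sort(rng.integers(0, length - len(motif),
                                          size=config.motifs_per_chrom))
            for start in starts:
                if any(abs(start - o) < len(motif) + 2 for o in occupied):
                    continue
                # avoid breaking a CG across the left boundary
                if start > 0 and seq[start - 1] == "C" and m[0] == "G":
                    continue
                end = start + len(motif)
                if end < length and m[-1] == "C" and seq[end] == "G":
                    continue
                seq[start:end] = m
                occupied.append(start)
                motif_rows.append((chrom, int(start), int(end), motif))
        genome[chrom] = "".join(seq)
    catalog = SiteCatalog.from_genome(genome, "CG")
    motifs = pd.DataFrame(motif_rows,
                          columns=["chrom", "start", "end", "motif"])
    return genome, catalog, motifs


def generate_truth(config: SyntheticConfig, genome: GenomeSequence,
                   catalog: SiteCatalog, motif_instances: pd.DataFrame,
                   rng: np.random.Generator | None = None) -> GroundTruth:
    """Per-(cluster, site) methylation probabilities.

    logit = block baseline (shared across clusters) + cluster-specific DMR
    shift + summed effects of motif instances containing the site.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    n_sites = len(catalog)
    pos0 = catalog.pos - 1

    lo, hi = config.baseline_logit_range
    baseline = np.zeros(n_sites)
    for chrom, (a, b) in catalog.chrom_ranges.items():
        length = len(genome[chrom])
        n_blocks = -(-length // config.baseline_block)
        block_logit = rng.uniform(lo, hi, size=n_blocks)
        baseline[a:b] = block_logit[pos0[a:b] // config.baseline_block]

    motif_effect = np.zeros(n_sites)
    affected = np.zeros(n_sites, dtype=bool)
    for chrom, start, end, motif in motif_instances.itertuples(index=False):
        a, b = catalog.chrom_ranges.get(chrom, (0, 0))
        inside = (pos0[a:b] >= start) & (pos0[a:b] < end)
        motif_effect[a:b][inside] += config.motifs[motif]
        affected[a:b][inside] = True

    dmr = np.zeros((config.n_clusters, n_sites))
    dmr_rows = []
    for k in range(config.n_clusters):
        for chrom, (a, b) in catalog.chrom_ranges.items():
            length = len(genome[chrom])
            n_here = max(1, round(config.n_dmr_per_cluster
                                  * length / sum(config.chrom_lengths.values())))
            starts = rng.integers(0, max(1, length - config.dmr_width),
                                  size=n_here)
            for start in starts:
                end = start + config.dmr_width
                inside = (pos0[a:b] >= start) & (pos0[a:b] < end)
                dmr[k, a:b][inside] += config.dmr_shift
                dmr_rows.append((chrom, int(start), int(end), k + 1,
                                 config.dmr_shift))

    logits = baseline[None, :] + dmr + motif_effect[None, :]
    probs = _sigmoid(logits)

    clusters = 1 + (np.arange(config.n_cells) % config.n_clusters)
    rng.shuffle(clusters)
    return GroundTruth(clusters, probs, affected, motif_effect, baseline, dmr,
                       pd.DataFrame(dmr_rows, columns=["chrom", "start", "end",
                                                       "cluster", "shift"]))


def sample_cells(config: SyntheticConfig, catalog: SiteCatalog,
                 truth: GroundTruth,
                 rng: np.random.Generator | None = None):
    """Draw per-cell states and sparse reads.

    Returns (call tables, BinaryStateTable of drawn-and-observed states,
    coverage report frame).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n_sites = len(catalog)
    tables, state_frames, report = [], [], []
    for i in range(config.n_cells):
        cell = f"cell{i:04d}"
        k = truth.cell_clusters[i] - 1
        states = (rng.random(n_sites) < truth.probs[k]).astype(np.uint8)
        observed = rng.random(n_sites) < config.coverage
        idx = np.flatnonzero(observed)
        depth = 1 + rng.poisson(config.read_depth_lambda, size=len(idx))
        mc = states[idx].astype(np.int64) * depth
        if config.discordance_rate > 0:
            mixed = rng.random(len(idx)) < config.discordance_rate
            depth = np.where(mixed, np.maximum(depth, 2), depth)
            mc = np.where(mixed & (depth >= 2),
                          1 + rng.integers(0, np.maximum(depth - 1, 1)),
                          states[idx] * depth)
            mc = np.minimum(mc, depth)
        frame = pd.DataFrame({
            "chrom": catalog.chrom[idx], "pos": catalog.pos[idx],
            "strand": catalog.strand[idx], "context": "CGN",
            "mc": mc, "cov": depth,
        })
        tables.append(MethylationCallTable(cell, frame))
        concordant = (mc == 0) | (mc == depth)
        state_frames.append(pd.DataFrame({
            "cell": cell,
            "chrom": catalog.chrom[idx][concordant],
            "pos": catalog.pos[idx][concordant],
            "strand": catalog.strand[idx][concordant],
            "state": (mc[concordant] > 0).astype(np.uint8),
        }))
        report.append({"cell": cell, "cluster": int(truth.cell_clusters[i]),
                       "n_observed": int(len(idx)),
                       "fraction_observed": len(idx) / n_sites})
    states = BinaryStateTable(pd.concat(state_frames, ignore_index=True))
    return tables, states, pd.DataFrame(report)


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """End-to-end generation from (config, seed)."""
    root = np.random.SeedSequence(config.seed)
    g_rng, t_rng, c_rng = (np.random.default_rng(s) for s in root.spawn(3))
    genome, catalog, motif_instances = generate_genome(config, g_rng)
    truth = generate_truth(config, genome, catalog, motif_instances, t_rng)
    tables, states, _report = sample_cells(config, catalog, truth, c_rng)
    return SyntheticDataset(config, genome, catalog, truth, tables, states)
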