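"""Synthetic multi-target single-cell fragment data with planted ground truth.

The generator emulates the structure of antibody-barcoded single-cell
tagmentation experiments: several cell types, several chromatin targets,
heavy-tailed per-cell depth, a uniform genomic background of fragments, and
planted gene-level enrichment (rate multipliers over gene windows) that the
downstream Poisson test should recover.  A separate barnyard generator plants
cross-species doublets for collision-rate estimation.

Fragments are placed by midpoint: midpoints fall uniformly on the genome at a
background rate per bp per cell, and uniformly on enriched gene windows at
``multiplier`` times that rate (the background contributes its own share, so
a multiplier of 1 plants nothing).  Fragment lengths are normal, truncated to
[30, 1000] bp.  Per-cell depth is a log-normal multiplier on all rates, which
reproduces the skewed unique-read distributions that motivate a fixed
per-cell unique-fragment QC cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio

MIN_FRAGMENT_LEN = 30
MAX_FRAGMENT_LEN = 1000


class ConfigurationError(ValueError):
    """The simulation configuration is inconsistent."""


@dataclass
class SimConfig:
    """Configuration for a multi-type, multi-target fragment simulation.

    Attributes
    ----------
    n_cells_per_type
        Cells simulated for each cell type.
    cell_types, targets
        Labels; at least one of each.
    genome_length
        Single simulated chromosome length in bp.
    genes
        DataFrame-like records ``(gene_id, chrom, strand, start, end)``.
    enrichment_map
        ``(cell_type, target) -> {gene_id: multiplier}`` with multipliers >= 1.
        A gene listed here receives fragments at ``multiplier x`` the
        background rate over its test window in cells of that type.
    background_rate
        Expected fragments per bp per cell per target, before the per-cell
        depth multiplier.
    fragment_length_mean, fragment_length_sd
        Parameters of the truncated-normal fragment length model (bp).
    depth_lognormal_mu, depth_lognormal_sigma
        Per-cell log-normal depth multiplier parameters (natural log scale);
        the default (0, 0.5) gives median 1 with a realistic right tail.
    upstream
        Upstream extension used to build enriched gene windows, matching the
        gene-window convention of the enrichment test.
    chrom
        Name of the simulated chromosome.
    seed
        Base seed for reproducibility.
    """

    n_cells_per_type: int
    cell_types: list[str]
    targets: list[str]
    genome_length: int
    genes: pd.DataFrame
    enrichment_map: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    background_rate: float = 5e-5
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 80.0
    depth_lognormal_mu: float = 0.0
    depth_lognormal_sigma: float = 0.5
    upstream: int = 1000
    chrom: str = "chr1"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells_per_type < 0:
            raise ConfigurationError("n_cells_per_type must be >= 0")
        if not self.cell_types:
            raise ConfigurationError("at least one cell type is required")
        if not self.targets:
            raise ConfigurationError("at least one target is required")
        if self.genome_length <= 0:
            raise ConfigurationError("genome_length must be positive")
        gene_ids = set(self.genes["gene_id"]) if len(self.genes) else set()
        if len(self.genes):
            if (self.genes["start"] < 0).any() or (self.genes["end"] > self.genome_length).any():
                raise ConfigurationError("gene intervals must lie within [0, genome_length)")
            if (self.genes["end"] <= self.genes["start"]).any():
                raise ConfigurationError("gene end must exceed start")
        for (ct, tgt), genes in self.enrichment_map.items():
            if ct not in self.cell_types:
                raise ConfigurationError(f"enrichment_map cell type {ct!r} unknown")
            if tgt not in self.targets:
                raise ConfigurationError(f"enrichment_map target {tgt!r} unknown")
            for g, mult in genes.items():
                if g not in gene_ids:
                    raise ConfigurationError(f"enrichment_map gene {g!r} not in gene table")
                if mult < 1:
                    raise ConfigurationError(f"multiplier for {g!r} must be >= 1")


@dataclass
class TruthTable:
    """Planted ground truth for a simulated dataset.

    ``cells``: one row per cell — ``cell, cell_type, species, is_doublet,
    depth_multiplier, n_fragments``.  ``enrichment``: one row per planted
    ``(cell, gene_id, target)`` triple (flag True only where the cell's type
    has that gene enriched for that target).
    """

    cells: pd.DataFrame
    enrichment: pd.DataFrame


def _empty_truth() -> TruthTable:
    cells = pd.DataFrame(
        columns=["cell", "cell_type", "species", "is_doublet",
                 "depth_multiplier", "n_fragments"]
    )
    enr = pd.DataFrame(columns=["cell", "gene_id", "target", "multiplier"])
    return TruthTable(cells=cells, enrichment=enr)


def _draw_lengths(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Truncated-normal fragment lengths in [MIN_FRAGMENT_LEN, MAX_FRAGMENT_LEN]."""
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    lengths = rng.normal(mean, sd, size=n)
    # resample the (rare) out-of-range draws rather than clipping, to avoid
    # probability mass piling up at the bounds
    bad = (lengths < MIN_FRAGMENT_LEN) | (lengths > MAX_FRAGMENT_LEN)
    while bad.any():
        lengths[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (lengths < MIN_FRAGMENT_LEN) | (lengths > MAX_FRAGMENT_LEN)
    return np.round(lengths).astype(np.int64)


def _fragments_from_midpoints(
    rng: np.random.Generator,
    midpoints: np.ndarray,
    genome_length: int,
    mean: float,
    sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Starts/ends from midpoints: start = floor(mid - len/2), clipped to genome."""
    lengths = _draw_lengths(rng, midpoints.size, mean, sd)
    starts = np.floor(midpoints - lengths / 2).astype(np.int64)
    ends = starts + lengths
    shift_left = np.maximum(0, -starts)
    starts += shift_left
    ends += shift_left
    shift_right = np.maximum(0, ends - genome_length)
    starts -= shift_right
    ends -= shift_right
    starts = np.maximum(starts, 0)
    return starts, ends


def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a multi-cell-type, multi-target fragment dataset.

    Returns the fragment set (already unique by construction with
    ``dup_count = 1``) and the :class:`TruthTable` of planted enrichments.
    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    windows = (
        fio.gene_windows(config.genes, upstream=config.upstream)
        if len(config.genes)
        else pd.DataFrame(columns=["gene_id", "window_start", "window_end", "length"])
    )
    win = windows.set_index("gene_id") if len(windows) else None

    cell_rows = []
    enr_rows = []
    frag_parts: list[pd.DataFrame] = []
    for ct in config.cell_types:
        for i in range(config.n_cells_per_type):
            cell_id = f"{ct}_{i:04d}"
            depth = float(rng.lognormal(config.depth_lognormal_mu,
                                        config.depth_lognormal_sigma))
            n_cell_frags = 0
            for tgt in config.targets:
                rate = config.background_rate * depth
                n_bg = rng.poisson(rate * config.genome_length)
                mids = [rng.uniform(0, config.genome_length, size=n_bg)]
                planted = config.enrichment_map.get((ct, tgt), {})
                for gene_id, mult in planted.items():
                    ws = int(win.loc[gene_id, "window_start"])
                    we = int(win.loc[gene_id, "window_end"])
                    extra = rng.poisson(rate * (mult - 1.0) * (we - ws))
                    if extra:
                        mids.append(rng.uniform(ws, we, size=extra))
                    enr_rows.append((cell_id, gene_id, tgt, float(mult)))
                midpoints = np.concatenate(mids) if mids else np.zeros(0)
                starts, ends = _fragments_from_midpoints(
                    rng, midpoints, config.genome_length,
                    config.fragment_length_mean, config.fragment_length_sd,
                )
                n_cell_frags += starts.size
                if starts.size:
                    frag_parts.append(
                        pd.DataFrame(
                            {
                                "chrom": config.chrom,
                                "start": starts,
                                "end": ends,
                                "cell": cell_id,
                                "target": tgt,
                                "dup_count": 1,
                            }
                        )
                    )
            cell_rows.append((cell_id, ct, "single", False, depth, n_cell_frags))

    if frag_parts:
        frags = pd.concat(frag_parts, ignore_index=True)[fio.FRAGMENT_COLUMNS]
    else:
        frags = fio.empty_fragments()
    truth = TruthTable(
        cells=pd.DataFrame(
            cell_rows,
            columns=["cell", "cell_type", "species", "is_doublet",
                     "depth_multiplier", "n_fragments"],
        ),
        enrichment=pd.DataFrame(
            enr_rows, columns=["cell", "gene_id", "target", "multiplier"]
        ),
    )
    return frags, truth


def simulate_species_mix(
    n_cells: int,
    doublet_rate: float,
    reads_per_cell: int,
    seed: int = 0,
    genome_length: int = 10_000_000,
    contamination_rate: float = 0.002,
    target: str = "H3K27me3",
    species_chroms: tuple[str, str] = ("hg19_chr1", "mm10_chr1"),
) -> tuple[pd.DataFrame, TruthTable]:
    """Simulate a barnyard (two-species) experiment.

    Each barcode is a cross-species doublet with probability ``doublet_rate``;
    a doublet's reads split Binomial(reads, 0.5) between species.  Singlets
    draw a species at random and carry a small binomial cross-contamination
    (``contamination_rate``) so their majority-species fraction stays >= 99%.
    Species is encoded in the chromosome-name prefix.
    """
    if not 0 <= doublet_rate <= 1:
        raise ConfigurationError("doublet_rate must be in [0, 1]")
    if reads_per_cell <= 0:
        raise ConfigurationError("reads_per_cell must be positive")
    rng = np.random.default_rng(seed)
    chrom_a, chrom_b = species_chroms
    frag_parts = []
    cell_rows = []
    for i in range(n_cells):
        cell_id = f"BC{i:05d}"
        is_doublet = bool(rng.random() < doublet_rate)
        if is_doublet:
            n_a = int(rng.binomial(reads_per_cell, 0.5))
            species = "doublet"
        else:
            own_is_a = bool(rng.random() < 0.5)
            n_contam = int(rng.binomial(reads_per_cell, contamination_rate))
            n_a = reads_per_cell - n_contam if own_is_a else n_contam
            species = "human" if own_is_a else "mouse"
        n_b = reads_per_cell - n_a
        for chrom, n in ((chrom_a, n_a), (chrom_b, n_b)):
            if n == 0:
                continue
            mids = rng.uniform(0, genome_length, size=n)
            starts, ends = _fragments_from_midpoints(rng, mids, genome_length, 250.0, 80.0)
            frag_parts.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": starts,
                        "end": ends,
                        "cell": cell_id,
                        "target": target,
                        "dup_count": 1,
                    }
                )
            )
        cell_rows.append((cell_id, "barnyard", species, is_doublet, 1.0, reads_per_cell))
    frags = (
        pd.concat(frag_parts, ignore_index=True)[fio.FRAGMENT_COLUMNS]
        if frag_parts
        else fio.empty_fragments()
    )
    truth = TruthTable(
        cells=pd.DataFrame(
            cell_rows,
            columns=["cell", "cell_type", "species", "is_doublet",
                     "depth_multiplier", "n_fragments"],
        ),
        enrichment=pd.DataFrame(columns=["cell", "gene_id", "target", "multiplier"]),
    )
    return frags, truth


def write_dataset(
    frags: pd.DataFrame, truth: TruthTable, directory: str | Path
) -> dict[str, Path]:
    """Write one fragment BED per target plus truth TSVs.

    Round-trips losslessly through :func:`multitag.io.read_fragments` (up to
    row order, which is coordinate-sorted on disk).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    targets = sorted(frags["target"].unique()) if len(frags) else []
    for tgt in targets:
        p = directory / f"fragments.{tgt}.bed"
        fio.write_fragments(frags[frags["target"] == tgt], p)
        paths[f"fragments:{tgt}"] = p
    cells_path = directory / "truth_cells.tsv"
    truth.cells.to_csv(cells_path, sep="\t", index=False)
    paths["truth_cells"] = cells_path
    enr_path = directory / "truth_enrichment.tsv"
    truth.enrichment.to_csv(enr_path, sep="\t", index=False)
    paths["truth_enrichment"] = enr_path
    return paths
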