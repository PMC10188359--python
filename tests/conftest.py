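import numpy as np
import pandas as pd
import pytest

from multitag import io as fio


def make_frags(rows):
    """Build a fragment DataFrame from (chrom, start, end, cell, target[, dup]) tuples."""
    full = [(r + (1,))[:6] for r in rows]
    return pd.DataFrame(full, columns=fio.FRAGMENT_COLUMNS)


@pytest.fixture
def gene_table():
    return pd.DataFrame(
        [
            ("geneA", "chr1", "+", 5000, 8000),
            ("geneB", "chr1", "-", 2000, 5000),
            ("geneC", "chr2", "+", 500, 900),
        ],
        columns=["gene_id", "chrom", "strand", "start", "end"],
    )


@pytest.fixture
def two_type_dataset():
    """Small two-cell-type simulation with disjoint planted enrichment."""
    from multitag import synth

    genes = pd.DataFrame(
        [(f"g{i:02d}", "chr1", "+", 400_000 * i + 50_000, 400_000 * i + 60_000)
         for i in range(10)],
        columns=["gene_id", "chrom", "strand", "start", "end"],
    )
    cfg = synth.SimConfig(
        n_cells_per_type=40,
        cell_types=["typeA", "typeB"],
        targets=["H3K27me3", "H3K36me3"],
        genome_length=5_000_000,
        genes=genes,
        enrichment_map={
            ("typeA", "H3K27me3"): {"g00": 50.0, "g01": 50.0},
            ("typeB", "H3K27me3"): {"g05": 50.0, "g06": 50.0},
        },
        background_rate=1e-4,
        seed=11,
    )
    frags, truth = synth.simulate_experiment(cfg)
    return cfg, frags, truth
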