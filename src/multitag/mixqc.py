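"""Barnyard (species-mixing) QC: per-cell species composition and collisions.

In a barnyard experiment cells of two species are mixed so that a barcode
capturing more than one cell usually captures cells of different species.
Such collisions are detected as barcodes whose majority species accounts for
less than a threshold fraction (default 90%, strict) of unique reads.
"""

from __future__ import annotations

from collections.abc import Mapping

import pandas as pd


def species_from_prefix(prefixes: Mapping[str, str]):
    """Build a chrom -> species mapper from reference-name prefixes.

    ``prefixes`` maps a chromosome-name prefix (e.g. ``"hg19_"``) to a
    species label.  The returned callable raises ``KeyError`` naming any
    chromosome no prefix matches.
    """

    def mapper(chrom: str) -> str:
        for prefix, species in prefixes.items():
            if chrom.startswith(prefix):
                return species
        raise KeyError(f"no species prefix matches chromosome {chrom!r}")

    return mapper


def species_fractions(
    frags: pd.DataFrame, species_of: Mapping[str, str] | callable
) -> pd.DataFrame:
    """Per-cell unique-read counts and majority fraction per species.

    Counts are pooled across targets within each cell.  ``species_of`` maps
    a reference name to a species label (a dict keyed by full chromosome
    name, or a callable such as :func:`species_from_prefix` output).

    Returns a DataFrame indexed by cell with one count column per species
    plus ``total``, ``max_fraction`` and ``majority_species``.
    """
    if len(frags) == 0:
        raise ValueError("species_fractions: empty fragment set")
    chroms = frags["chrom"].unique()
    if callable(species_of):
        mapping = {c: species_of(c) for c in chroms}
    else:
        missing = [c for c in chroms if c not in species_of]
        if missing:
            raise KeyError(f"chromosome(s) not mapped to a species: {missing}")
        mapping = {c: species_of[c] for c in chroms}
    work = frags.assign(species=frags["chrom"].map(mapping))
    counts = work.groupby(["cell", "species"]).size().unstack(fill_value=0)
    total = counts.sum(axis=1)
    out = counts.copy()
    out["total"] = total
    out["max_fraction"] = counts.max(axis=1) / total
    out["majority_species"] = counts.idxmax(axis=1)
    return out


def collision_rate(
    profiles: pd.DataFrame, threshold: float = 0.90
) -> tuple[int, int, float]:
    """Cross-species collision rate among profiled cells.

    A cell is a collision iff its majority-species fraction is strictly below
    ``threshold`` (the "<90% of reads from a single species" rule).

    Returns ``(n_collisions, n_cells, rate)``.
    """
    if len(profiles) == 0:
        raise ValueError("collision_rate: no cell profiles")
    collided = profiles["max_fraction"] < threshold
    n_coll = int(collided.sum())
    n_cells = int(len(profiles))
    return n_coll, n_cells, n_coll / n_cells


def format_rate(rate: float) -> str:
    """One-decimal percentage, half-up rounding (display convention)."""
    import decimal

    pct = decimal.Decimal(str(rate * 100)).quantize(
        decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
    )
    return f"{pct}%"
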