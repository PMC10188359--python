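"""Fragment-file I/O, deduplication, per-cell QC and gene test windows.

Fragments follow the Cell Ranger convention: BED-style, tab-separated,
0-based half-open coordinates, fourth column the cell barcode, optional fifth
column the number of PCR duplicates collapsed into the fragment.  In memory a
fragment set is a :class:`pandas.DataFrame` with columns
``chrom, start, end, cell, target, dup_count`` — the ``target`` label records
which chromatin target's antibody barcode produced the fragment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end", "cell", "target", "dup_count"]

#: key on which fragments are unique after deduplication; the target label is
#: part of the key because the targets are separate assays sharing a cell.
UNIQUE_KEY = ["chrom", "start", "end", "cell", "target"]


class FragmentParseError(ValueError):
    """A fragment line violated the BED fragment-file contract."""


def empty_fragments() -> pd.DataFrame:
    """An empty fragment set with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "chrom": pd.Series([], dtype=str),
            "start": pd.Series([], dtype=np.int64),
            "end": pd.Series([], dtype=np.int64),
            "cell": pd.Series([], dtype=str),
            "target": pd.Series([], dtype=str),
            "dup_count": pd.Series([], dtype=np.int64),
        }
    )


def as_fragments(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce/validate a DataFrame into the fragment-set contract."""
    missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns and c != "dup_count"]
    if missing:
        raise ValueError(f"fragment frame missing columns: {missing}")
    out = df.copy()
    if "dup_count" not in out.columns:
        out["dup_count"] = 1
    out = out[FRAGMENT_COLUMNS]
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    out["dup_count"] = out["dup_count"].astype(np.int64)
    bad = out["end"] <= out["start"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"fragment row {i}: end <= start")
    return out


def read_fragments(path: str | Path, target: str) -> pd.DataFrame:
    """Read one per-target fragment BED file.

    Parameters
    ----------
    path
        Tab-separated BED: chrom, start, end, cell barcode, optional
        duplicate count.  A missing fifth column means ``dup_count = 1``.
    target
        Chromatin-target label attached to every fragment in the file.

    Raises
    ------
    FragmentParseError
        Naming the 1-based line number, for non-integer coordinates,
        ``end <= start`` or fewer than four columns.
    """
    path = Path(path)
    rows: list[tuple[str, int, int, str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FragmentParseError(
                    f"{path}:{lineno}: expected >= 4 tab-separated columns, got {len(fields)}"
                )
            chrom, s, e, cell = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FragmentParseError(
                    f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}"
                ) from exc
            if end <= start or start < 0:
                raise FragmentParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})"
                )
            if not cell:
                raise FragmentParseError(f"{path}:{lineno}: empty cell barcode")
            if len(fields) >= 5 and fields[4] != "":
                try:
                    dup = int(fields[4])
                except ValueError as exc:
                    raise FragmentParseError(
                        f"{path}:{lineno}: non-integer duplicate count {fields[4]!r}"
                    ) from exc
            else:
                dup = 1
            rows.append((chrom, start, end, cell, target, dup))
    if not rows:
        return empty_fragments()
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def write_fragments(frags: pd.DataFrame, path: str | Path) -> Path:
    """Write a single-target fragment set as a coordinate-sorted BED file."""
    path = Path(path)
    out = frags.sort_values(["chrom", "start", "end", "cell"], kind="mergesort")
    out[["chrom", "start", "end", "cell", "dup_count"]].to_csv(
        path, sep="\t", header=False, index=False
    )
    return path


def deduplicate(frags: pd.DataFrame) -> pd.DataFrame:
    """Collapse fragments sharing ``(chrom, start, end, cell, target)``.

    The surviving fragment's ``dup_count`` is the total duplicate mass of the
    collapsed group, so total ``dup_count`` is conserved and the operation is
    idempotent.
    """
    if len(frags) == 0:
        return empty_fragments()
    out = (
        frags.groupby(UNIQUE_KEY, as_index=False, sort=False)["dup_count"]
        .sum()
        .reset_index(drop=True)
    )
    return out[FRAGMENT_COLUMNS]


@dataclass
class CellQC:
    """Per-cell QC summary across targets.

    Attributes
    ----------
    unique_counts
        cells x targets DataFrame of unique fragment counts (``f_i`` per
        target when counted per-target).
    median_length
        cells x targets DataFrame of median fragment lengths in bp (``L_i``).
    passed
        Boolean Series per cell: True iff every required target's unique
        count meets its threshold.
    min_unique
        The effective per-target thresholds applied.
    """

    unique_counts: pd.DataFrame
    median_length: pd.DataFrame
    passed: pd.Series
    min_unique: dict[str, int] = field(default_factory=dict)

    @property
    def passing_cells(self) -> list[str]:
        return list(self.passed.index[self.passed])


def cell_qc(
    frags: pd.DataFrame,
    required_targets: list[str],
    min_unique: int = 100,
    relax: dict[str, int] | None = None,
) -> CellQC:
    """Count unique fragments per cell and target and apply the QC filter.

    A cell passes iff it has at least ``min_unique`` unique fragments for
    every required target.  ``relax`` overrides the threshold for individual
    targets (e.g. a lower cutoff for a sparse mark to keep more cells).

    ``frags`` is expected to be deduplicated; counts are row counts.
    """
    available = sorted(frags["target"].unique())
    missing = [t for t in required_targets if t not in available]
    if missing:
        raise ValueError(
            f"required target(s) {missing} absent from data; available: {available}"
        )
    thresholds = {t: int(min_unique) for t in required_targets}
    if relax:
        unknown = [t for t in relax if t not in thresholds]
        if unknown:
            raise ValueError(f"relax given for non-required target(s): {unknown}")
        thresholds.update({t: int(v) for t, v in relax.items()})

    lengths = frags["end"] - frags["start"]
    work = frags.assign(_len=lengths)
    counts = (
        work.groupby(["cell", "target"], sort=True)
        .size()
        .unstack(fill_value=0)
        .astype(np.int64)
    )
    med = work.groupby(["cell", "target"], sort=True)["_len"].median().unstack()
    for t in required_targets:
        if t not in counts.columns:  # pragma: no cover - guarded above
            counts[t] = 0
    passed = pd.Series(True, index=counts.index)
    for t, thr in thresholds.items():
        passed &= counts[t] >= thr
    return CellQC(unique_counts=counts, median_length=med, passed=passed,
                  min_unique=thresholds)


def filter_cells(frags: pd.DataFrame, cells: list[str]) -> pd.DataFrame:
    """Restrict a fragment set to the given cells."""
    return frags[frags["cell"].isin(set(cells))].reset_index(drop=True)


def gene_windows(annotation: pd.DataFrame, upstream: int = 1000) -> pd.DataFrame:
    """Build strand-aware gene test windows.

    Each gene's window runs from ``upstream`` bp upstream of its farthest
    distal TSS to its TES: for a ``+`` strand gene ``[start, end)`` the window
    is ``[start - upstream, end)``; for ``-`` strand, ``[start, end + upstream)``.
    Windows are clipped at 0.

    Parameters
    ----------
    annotation
        DataFrame with columns ``gene_id, chrom, start, end, strand``
        (gene body in 0-based half-open coordinates, farthest-distal TSS at
        ``start`` for + genes and ``end`` for - genes).

    Returns
    -------
    DataFrame with ``gene_id, chrom, strand, window_start, window_end, length``.
    """
    ann = annotation.copy()
    bad = ~ann["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(
            f"unknown strand value(s): {sorted(ann.loc[bad, 'strand'].unique())}"
        )
    plus = ann["strand"] == "+"
    ws = np.where(plus, ann["start"] - upstream, ann["start"])
    we = np.where(plus, ann["end"], ann["end"] + upstream)
    ws = np.maximum(ws, 0)
    out = pd.DataFrame(
        {
            "gene_id": ann["gene_id"].to_numpy(),
            "chrom": ann["chrom"].to_numpy(),
            "strand": ann["strand"].to_numpy(),
            "window_start": ws.astype(np.int64),
            "window_end": we.astype(np.int64),
        }
    )
    out["length"] = out["window_end"] - out["window_start"]
    return out


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read a BED6-like gene table (chrom, start, end, gene_id, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        usecols=[0, 1, 2, 3, 4, 5],
        comment="#",
    )
    return df[["gene_id", "chrom", "start", "end", "strand"]]


def read_peaks(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ peak file; only chrom/start/end are used."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    return out


def _overlaps_any(frags: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask: does each fragment overlap (>= 1 bp) any interval?"""
    mask = np.zeros(len(frags), dtype=bool)
    if len(frags) == 0 or len(intervals) == 0:
        return mask
    fchrom = frags["chrom"].to_numpy()
    fstart = frags["start"].to_numpy()
    fend = frags["end"].to_numpy()
    for chrom, sub in intervals.groupby("chrom"):
        sel = np.flatnonzero(fchrom == chrom)
        if sel.size == 0:
            continue
        # merge intervals so a sorted sweep suffices
        ivs = sub.sort_values("start")[["start", "end"]].to_numpy()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        # candidate: last merged interval starting before the fragment end
        idx = np.searchsorted(starts, fend[sel], side="left") - 1
        ok = idx >= 0
        hit = np.zeros(sel.size, dtype=bool)
        hit[ok] = ends[idx[ok]] > fstart[sel[ok]]
        mask[sel] = hit
    return mask


def frip(frags: pd.DataFrame, peaks: pd.DataFrame) -> pd.Series:
    """Fraction of unique fragments overlapping any peak, per target.

    Targets with zero fragments yield NaN (the ratio is undefined).
    """
    if len(frags) == 0:
        warnings.warn("frip: empty fragment set; returning empty result")
        return pd.Series(dtype=float)
    inside = _overlaps_any(frags, peaks)
    return frags.assign(_in=inside).groupby("target")["_in"].mean().rename("frip")


def peak_target_purity(
    frags: pd.DataFrame,
    peaks: pd.DataFrame,
    expected_target: str,
    purity_threshold: float = 0.8,
) -> tuple[pd.DataFrame, float]:
    """Per-peak on-target purity and the fraction of peaks meeting a threshold.

    For each peak, purity = unique fragments of ``expected_target``
    overlapping the peak / all unique fragments overlapping it.  Peaks with no
    overlapping fragments are excluded from the summary fraction.

    Returns
    -------
    (per-peak DataFrame with ``chrom, start, end, n_fragments, purity``,
    fraction of assessable peaks with purity >= ``purity_threshold``).
    The fraction is NaN when no peak is assessable.
    """
    records = []
    fchrom = frags["chrom"].to_numpy()
    fstart = frags["start"].to_numpy()
    fend = frags["end"].to_numpy()
    is_expected = (frags["target"] == expected_target).to_numpy()
    for _, peak in peaks.iterrows():
        sel = (fchrom == peak["chrom"]) & (fstart < peak["end"]) & (fend > peak["start"])
        n = int(sel.sum())
        purity = float(is_expected[sel].sum() / n) if n > 0 else np.nan
        records.append((peak["chrom"], peak["start"], peak["end"], n, purity))
    per_peak = pd.DataFrame(
        records, columns=["chrom", "start", "end", "n_fragments", "purity"]
    )
    assessable = per_peak["n_fragments"] > 0
    if assessable.sum() == 0:
        return per_peak, float("nan")
    frac = float((per_peak.loc[assessable, "purity"] >= purity_threshold).mean())
    return per_peak, frac
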