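"""Group-level and trajectory-level comparisons.

Two families of analysis: (1) partition cells into 'low' and 'high' groups by
a target's per-cell read fraction and test per-gene differential enrichment
(log fold change with pseudocount, two-sided t-test, no multiple-testing
correction); (2) evaluate inferred pseudotime trajectories against known
differentiation timepoints via the misassignment frequency and the pairwise
inversion (discordance) frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def partition_by_fraction(
    fractions: pd.Series,
    method: str = "median",
    quantile: float = 0.5,
    threshold: float | None = None,
) -> tuple[list, list]:
    """Split cells into low/high groups by a per-cell target fraction.

    ``method="median"``: cells at or below the median go to the low group
    (ties to low, for determinism).  ``method="quantile"`` uses the given
    quantile the same way; ``method="threshold"`` uses a fixed cutoff.

    Returns ``(low_cells, high_cells)``.
    """
    if len(fractions) < 2:
        raise ValueError("need at least 2 cells to partition")
    vals = fractions.astype(float)
    if vals.nunique() == 1:
        raise ValueError("all fractions identical; no partition exists")
    if method == "median":
        cut = vals.median()
    elif method == "quantile":
        cut = vals.quantile(quantile)
    elif method == "threshold":
        if threshold is None:
            raise ValueError("threshold method requires a threshold value")
        cut = threshold
    else:
        raise ValueError(f"unknown method {method!r}")
    low = vals.index[vals <= cut].tolist()
    high = vals.index[vals > cut].tolist()
    if not high:
        raise ValueError("degenerate partition: high group empty")
    return low, high


@dataclass
class GroupComparison:
    gene_id: str
    mean_low: float
    mean_high: float
    lfc: float
    t: float
    p: float
    degenerate: bool

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(self.p))


def differential_enrichment(
    low_cells: list,
    high_cells: list,
    norm_counts: pd.DataFrame,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Per-gene differential enrichment between two cell groups.

    ``norm_counts`` is a genes x cells matrix of per-cell normalized counts
    for one target.  For each gene:

        LFC = log2((mean_low + eps) / (mean_high + eps))

    and a two-sided two-sample (pooled-variance) t-test on the per-cell
    values.  When both groups are constant and equal the t statistic is
    undefined; the convention is p = 1 with the degenerate flag set.  No
    multiple-testing correction is applied.
    """
    if len(low_cells) < 2 or len(high_cells) < 2:
        raise ValueError("each group needs at least 2 cells")
    missing = [c for c in [*low_cells, *high_cells] if c not in norm_counts.columns]
    if missing:
        raise ValueError(f"cell(s) absent from counts: {missing[:5]}")
    rows = []
    for gene_id, row in norm_counts.iterrows():
        lo = row[low_cells].to_numpy(dtype=float)
        hi = row[high_cells].to_numpy(dtype=float)
        mean_low, mean_high = lo.mean(), hi.mean()
        lfc = float(np.log2((mean_low + eps) / (mean_high + eps)))
        degenerate = lo.std() == 0 and hi.std() == 0
        if degenerate:
            t, p = 0.0, 1.0
            if mean_low != mean_high:
                # constant but different groups: infinitely significant in the
                # t formalism; report the smallest representable p instead
                t, p = np.inf if mean_low > mean_high else -np.inf, np.nextafter(0, 1)
        else:
            t, p = stats.ttest_ind(lo, hi, equal_var=True)
        rows.append((gene_id, mean_low, mean_high, lfc, float(t), float(p), degenerate))
    out = pd.DataFrame(
        rows, columns=["gene_id", "mean_low", "mean_high", "lfc", "t", "p", "degenerate"]
    )
    out["neg_log10_p"] = -np.log10(out["p"])
    return out


def trajectory_assignment_error(
    cells: pd.DataFrame, truth_map: dict[str, str]
) -> tuple[pd.Series, float]:
    """Frequency of cells assigned to the wrong trajectory.

    ``cells`` needs columns ``cell_type`` and ``trajectory`` (the inferred
    assignment); ``truth_map`` maps each cell type to its correct trajectory.

    Returns (per-correct-trajectory misassignment frequency, pooled
    frequency).  Trajectories with no cells are excluded with a warning.
    """
    unknown = sorted(set(cells["cell_type"]) - set(truth_map))
    if unknown:
        raise ValueError(f"cell type(s) missing from truth_map: {unknown}")
    work = cells.assign(_correct=cells["cell_type"].map(truth_map))
    work["_mis"] = work["trajectory"] != work["_correct"]
    per_traj = work.groupby("_correct")["_mis"].mean().rename("misassignment")
    all_traj = set(truth_map.values())
    missing = sorted(all_traj - set(per_traj.index))
    if missing:
        warnings.warn(f"trajectory(ies) with no cells excluded: {missing}")
    overall = float(work["_mis"].mean())
    return per_traj, overall


def inversion_frequency(
    timepoints: np.ndarray | pd.Series, pseudotimes: np.ndarray | pd.Series
) -> float:
    """Pairwise inversion frequency of pseudotime against known timepoints.

    Over all cell pairs with distinct known timepoints, the fraction whose
    pseudotime ordering contradicts the timepoint ordering; pseudotime ties
    count as half discordant (Kendall-style).  0 when pseudotime is weakly
    monotone in timepoint, 1 when fully reversed.  Invariant under strictly
    monotone transforms of pseudotime.
    """
    t = np.asarray(timepoints, dtype=float)
    pt = np.asarray(pseudotimes, dtype=float)
    if t.shape != pt.shape:
        raise ValueError("timepoints and pseudotimes must have equal length")
    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct known timepoints")
    dt = np.sign(t[:, None] - t[None, :])
    dp = np.sign(pt[:, None] - pt[None, :])
    iu = np.triu_indices(t.size, k=1)
    comparable = dt[iu] != 0
    n_comp = int(comparable.sum())
    disc = (dt[iu][comparable] * dp[iu][comparable] < 0).sum()
    ties = (dp[iu][comparable] == 0).sum()
    return float((disc + 0.5 * ties) / n_comp)


def inversion_by_trajectory(cells: pd.DataFrame) -> pd.Series:
    """Inversion frequency per trajectory.

    ``cells`` needs columns ``trajectory``, ``timepoint`` and ``pseudotime``;
    each trajectory is evaluated on its own cells.  Trajectories with fewer
    than 2 distinct timepoints are skipped with a warning.
    """
    out = {}
    for traj, sub in cells.groupby("trajectory"):
        if sub["timepoint"].nunique() < 2:
            warnings.warn(f"trajectory {traj!r}: fewer than 2 distinct timepoints; skipped")
            continue
        out[traj] = inversion_frequency(sub["timepoint"], sub["pseudotime"])
    return pd.Series(out, name="inversion_frequency")
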