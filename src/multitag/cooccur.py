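"""Per-cell, per-gene, per-target Poisson enrichment and co-occurrence stats.

The central statistic asks, for each (cell, gene, target) triple, whether the
``r`` unique fragments of that target overlapping the gene's test window are
more than expected from the cell's genome-wide coverage.  Both sides are put
on a per-bp coverage-depth scale:

    x    = r * L_i / L_gene      observed mean coverage depth over the gene
    mu_i = L_i * f_i / L_genome  expected genome-wide per-bp coverage

where ``L_i`` is the cell's median fragment length, ``f_i`` the number of
fragments mapping in the cell (per target by default), ``L_gene`` the gene
window length and ``L_genome`` the reference length.  The p-value is the
upper Poisson tail ``P(Poisson(mu_i) >= ceil(x))`` (a continuous-tail variant
via the regularized incomplete gamma function is also provided, since
``x`` is generally non-integer and Poisson support is not).  One
Benjamini-Hochberg correction is applied over all triples in a run, and a
triple is called enriched when ``q < alpha`` (default 0.01).

Enrichment flags feed the cross-mark statistics: per-cell bivalency scores
(summed normalized counts over genes where a repressive and an active mark
are jointly enriched) and per-cell Cramér's V association between the
enrichment patterns of two targets across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

NORM_SCALE = 1e4  # normalized counts are per-cell counts scaled to this total per target


def count_gene_overlaps(
    frags: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Count unique fragments overlapping each gene window, per cell and target.

    A fragment counts for every window it overlaps by >= 1 bp (half-open
    intervals), so a fragment spanning two genes contributes to both.
    Only non-zero triples are returned.

    ``windows`` is the output of :func:`multitag.io.gene_windows`.
    """
    if len(windows) == 0:
        raise ValueError("empty gene window list")
    parts = []
    for chrom, sub in frags.groupby("chrom"):
        wsub = windows[windows["chrom"] == chrom]
        if len(wsub) == 0:
            continue
        fstart = sub["start"].to_numpy()
        fend = sub["end"].to_numpy()
        for _, w in wsub.iterrows():
            hit = (fstart < w["window_end"]) & (fend > w["window_start"])
            if not hit.any():
                continue
            counts = (
                sub.loc[hit].groupby(["cell", "target"]).size().rename("r").reset_index()
            )
            counts["gene_id"] = w["gene_id"]
            parts.append(counts)
    if not parts:
        return pd.DataFrame(columns=["cell", "target", "gene_id", "r"])
    out = pd.concat(parts, ignore_index=True)
    return out[["cell", "target", "gene_id", "r"]]


def poisson_test(
    r, L_i, f_i, L_gene, L_genome, method: str = "ceil"
):
    """Upper-tail Poisson p-value for fragment accumulation in a gene window.

    Vectorised over numpy-broadcastable inputs.  ``method="ceil"`` evaluates
    ``P(Poisson(mu_i) >= ceil(x))`` (so ``r = 0`` gives ``p = 1`` exactly);
    ``method="continuous"`` evaluates the regularized upper incomplete gamma
    tail at the non-integer ``x``.  Computation stays in scipy's log-space
    tail routines, so tiny p-values do not underflow to 0 prematurely.
    """
    r = np.asarray(r, dtype=float)
    L_i = np.asarray(L_i, dtype=float)
    f_i = np.asarray(f_i, dtype=float)
    L_gene = np.asarray(L_gene, dtype=float)
    L_genome = np.asarray(L_genome, dtype=float)
    if np.any(L_gene <= 0) or np.any(L_genome <= 0) or np.any(L_i <= 0) or np.any(f_i <= 0):
        raise ValueError("L_gene, L_genome, L_i and f_i must be positive")
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    x = r * L_i / L_gene
    mu = L_i * f_i / L_genome
    if method == "ceil":
        k = np.ceil(x)
        # P(X >= k) = sf(k - 1); k = 0 -> upper tail over full support -> 1
        p = stats.poisson.sf(k - 1, mu)
    elif method == "continuous":
        # P(X >= x) for continuous x via regularized lower incomplete gamma:
        # gammainc(x, mu) = P(Poisson(mu) >= x) at integer x, smooth between
        p = np.where(x <= 0, 1.0, special.gammainc(np.maximum(x, 1e-300), mu))
    else:
        raise ValueError(f"unknown method {method!r}")
    return p if p.shape else float(p)


def bh_adjust(pvals, alpha: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the significant set.

    Returns ``(q, significant)`` with ``significant = q < alpha`` (strict).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < alpha


@dataclass
class EnrichmentResult:
    """All (cell, gene, target) tests from one run.

    ``table`` columns: cell, gene_id, target, r, norm (per-cell counts scaled
    to ``NORM_SCALE`` total per target), x, mu, p, q, enriched.  The BH
    family is the whole table.
    """

    table: pd.DataFrame
    alpha: float
    L_genome: int
    targets: list[str]
    genes: list[str]

    def flags(self, target: str) -> pd.DataFrame:
        """Genes x cells boolean enrichment flags for one target."""
        sub = self.table[self.table["target"] == target]
        return (
            sub.pivot_table(index="gene_id", columns="cell", values="enriched",
                            aggfunc="first", fill_value=False)
            .astype(bool)
        )


def enrichment_tests(
    frags: pd.DataFrame,
    windows: pd.DataFrame,
    L_genome: int,
    alpha: float = 0.01,
    method: str = "ceil",
    per_target_depth: bool = True,
) -> EnrichmentResult:
    """Run the Poisson enrichment test for every (cell, gene, target) triple.

    The test family is the full grid of observed cells x gene windows x
    targets (triples with no overlapping fragments enter with ``r = 0`` and
    ``p = 1``), and one BH correction spans the family.

    ``per_target_depth=True`` computes ``f_i`` and ``L_i`` per (cell, target);
    otherwise they pool all targets in the cell.
    """
    if len(frags) == 0:
        raise ValueError("empty fragment set")
    overlaps = count_gene_overlaps(frags, windows)

    lengths = frags["end"] - frags["start"]
    by = ["cell", "target"] if per_target_depth else ["cell"]
    depth = frags.assign(_len=lengths).groupby(by).agg(
        f_i=("_len", "size"), L_i=("_len", "median")
    ).reset_index()

    cells_targets = frags[["cell", "target"]].drop_duplicates()
    grid = cells_targets.merge(windows[["gene_id", "length"]], how="cross")
    grid = grid.merge(overlaps, on=["cell", "target", "gene_id"], how="left")
    grid["r"] = grid["r"].fillna(0).astype(np.int64)
    grid = grid.merge(depth, on=by, how="left")

    p = poisson_test(
        grid["r"], grid["L_i"], grid["f_i"], grid["length"], L_genome, method=method
    )
    grid["x"] = grid["r"] * grid["L_i"] / grid["length"]
    grid["mu"] = grid["L_i"] * grid["f_i"] / L_genome
    grid["p"] = p
    q, sig = bh_adjust(grid["p"].to_numpy(), alpha)
    grid["q"] = q
    grid["enriched"] = sig
    grid["norm"] = grid["r"] * NORM_SCALE / grid["f_i"]
    table = grid.rename(columns={"length": "L_gene"})[
        ["cell", "gene_id", "target", "r", "norm", "L_i", "f_i", "L_gene",
         "x", "mu", "p", "q", "enriched"]
    ]
    return EnrichmentResult(
        table=table,
        alpha=alpha,
        L_genome=int(L_genome),
        targets=sorted(frags["target"].unique()),
        genes=list(windows["gene_id"]),
    )


def target_proportions(frags: pd.DataFrame) -> pd.DataFrame:
    """Per-cell fraction of unique reads from each target.

    Cells x targets DataFrame; rows sum to 1.  Cells with zero total unique
    reads are excluded with a warning.
    """
    counts = frags.groupby(["cell", "target"]).size().unstack(fill_value=0)
    total = counts.sum(axis=1)
    empty = total == 0
    if empty.any():
        import warnings

        warnings.warn(f"excluding {int(empty.sum())} cell(s) with zero unique reads")
        counts = counts[~empty]
        total = total[~empty]
    return counts.div(total, axis=0)


def bivalency_score(
    result: EnrichmentResult, repressive: str, active: list[str]
) -> pd.Series:
    """Per-cell bivalency: summed normalized counts in jointly-enriched genes.

    A gene is in a bivalent context for a cell when the repressive target and
    at least one active target are both flagged enriched in that gene in that
    cell.  The score sums the normalized counts of every enriched target
    (repressive plus enriched actives) over those genes; cells with no
    bivalent gene score 0.
    """
    known = set(result.targets)
    for t in [repressive, *active]:
        if t not in known:
            raise ValueError(f"unknown target {t!r}; available: {sorted(known)}")
    tab = result.table
    enr = tab[tab["enriched"]]
    rep = enr[enr["target"] == repressive][["cell", "gene_id"]]
    act = enr[enr["target"].isin(active)][["cell", "gene_id"]].drop_duplicates()
    bivalent = rep.merge(act, on=["cell", "gene_id"])  # (cell, gene) pairs
    cells = pd.Index(sorted(tab["cell"].unique()), name="cell")
    if len(bivalent) == 0:
        return pd.Series(0.0, index=cells, name="bivalency")
    contrib = enr.merge(bivalent, on=["cell", "gene_id"])
    score = contrib.groupby("cell")["norm"].sum()
    return score.reindex(cells, fill_value=0.0).rename("bivalency")


@dataclass
class AssociationResult:
    cell: str
    target_a: str
    target_b: str
    table: np.ndarray  # 2x2 contingency over genes
    n: int
    chi2: float
    v: float
    degenerate: bool


def _cramers_v_2x2(table: np.ndarray) -> tuple[float, float, bool]:
    """(chi2, V, degenerate) for a 2x2 table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if n == 0 or np.any(row == 0) or np.any(col == 0):
        return 0.0, 0.0, True
    expected = np.outer(row, col) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    v = float(np.sqrt(chi2 / n))  # min(k,c)-1 = 1 for a 2x2 table
    return chi2, v, False


def cramers_v(
    result: EnrichmentResult, cell: str, target_a: str, target_b: str
) -> AssociationResult:
    """Cramér's V between two targets' gene-enrichment patterns in one cell.

    Builds the 2x2 table (enriched for a?, enriched for b?) over the genes
    tested in that cell; ``V = sqrt(chi2 / n)`` for a 2x2 table, with chi2
    uncorrected.  A zero marginal (e.g. a target enriched nowhere in the
    cell) yields V = 0 with the degenerate flag set.
    """
    tab = result.table[result.table["cell"] == cell]
    if len(tab) == 0:
        raise ValueError(f"unknown cell {cell!r}")
    a = tab[tab["target"] == target_a].set_index("gene_id")["enriched"]
    b = tab[tab["target"] == target_b].set_index("gene_id")["enriched"]
    genes = a.index.intersection(b.index)
    if len(genes) < 2:
        raise ValueError(f"cell {cell!r}: fewer than 2 genes with data for both targets")
    av = a.loc[genes].to_numpy()
    bv = b.loc[genes].to_numpy()
    table = np.array(
        [
            [(av & bv).sum(), (av & ~bv).sum()],
            [(~av & bv).sum(), (~av & ~bv).sum()],
        ],
        dtype=float,
    )
    chi2, v, degenerate = _cramers_v_2x2(table)
    return AssociationResult(
        cell=cell, target_a=target_a, target_b=target_b, table=table,
        n=int(len(genes)), chi2=chi2, v=v, degenerate=degenerate,
    )


def cramers_v_all(
    result: EnrichmentResult, target_a: str, target_b: str
) -> pd.DataFrame:
    """Per-cell Cramér's V for one target pair (long-format DataFrame)."""
    rows = []
    for cell in sorted(result.table["cell"].unique()):
        r = cramers_v(result, cell, target_a, target_b)
        rows.append((cell, target_a, target_b, r.n, r.chi2, r.v, r.degenerate))
    return pd.DataFrame(
        rows, columns=["cell", "target_a", "target_b", "n", "chi2", "v", "degenerate"]
    )
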