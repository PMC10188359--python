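"""Cell typing by latent semantic indexing of genome-window fragment counts.

The pipeline mirrors the standard sparse-chromatin LSI recipe: fragments are
counted in fixed genomic windows (default 50 kb), the windows with the
largest aggregate counts are kept (default top 40%), counts are scaled by
TF-IDF and log-transformed, and the matrix is decomposed by SVD.  Dimensions
whose singular value exceeds a fixed fraction (default 0.2%) of the sum of
all singular values are retained; per-cell coordinates in those dimensions
feed UMAP for visualisation and k-means for clustering, with normalized
mutual information (NMI) against known labels as the evaluation metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.metrics.cluster import contingency_matrix, normalized_mutual_info_score


@dataclass
class CountMatrix:
    """Windows x cells unique-fragment counts for one chromatin target."""

    windows: pd.DataFrame  # columns chrom, start, end
    cells: np.ndarray
    counts: sp.csr_matrix  # shape (n_windows, n_cells)
    bin_size: int
    target: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class EmbeddingModel:
    """SVD embedding of a transformed count matrix.

    ``coords`` holds per-cell coordinates (cells x retained dims), computed
    as singular value times right-singular vector for each retained
    dimension.
    """

    cells: np.ndarray
    singular_values: np.ndarray
    n_retained: int
    coords: np.ndarray
    retain_frac: float
    idf: np.ndarray | None = None
    window_index: pd.DataFrame | None = None
    umap_coords: np.ndarray | None = None
    cluster_labels: np.ndarray | None = None


@dataclass
class ClusterEval:
    nmi: float
    contingency: pd.DataFrame


def bin_counts(
    frags: pd.DataFrame, genome_sizes: dict[str, int] | pd.Series, bin_size: int = 50_000
) -> CountMatrix:
    """Count fragments of one target in fixed non-overlapping genome windows.

    A fragment is counted once in every window it overlaps by >= 1 bp; the
    final partial window of each chromosome is included.
    """
    if isinstance(genome_sizes, pd.Series):
        genome_sizes = genome_sizes.to_dict()
    targets = frags["target"].unique() if len(frags) else np.array([])
    if len(targets) > 1:
        raise ValueError(f"bin_counts expects a single target, got {sorted(targets)}")
    target = str(targets[0]) if len(targets) else ""
    unknown = [c for c in frags["chrom"].unique() if c not in genome_sizes]
    if unknown:
        raise ValueError(f"chromosome(s) absent from genome sizes: {unknown}")

    # global window table, ordered by (chrom, start)
    win_rows = []
    offsets: dict[str, int] = {}
    for chrom in sorted(genome_sizes):
        size = int(genome_sizes[chrom])
        n_win = max(1, -(-size // bin_size))  # ceil; final partial window kept
        offsets[chrom] = len(win_rows)
        for w in range(n_win):
            win_rows.append((chrom, w * bin_size, min((w + 1) * bin_size, size)))
    windows = pd.DataFrame(win_rows, columns=["chrom", "start", "end"])

    cells = np.asarray(sorted(frags["cell"].unique())) if len(frags) else np.asarray([])
    cell_idx = {c: j for j, c in enumerate(cells)}
    n_windows = len(windows)
    if len(frags) == 0:
        return CountMatrix(windows, cells, sp.csr_matrix((n_windows, 0), dtype=np.int64),
                           bin_size, target)

    rows_acc: list[np.ndarray] = []
    cols_acc: list[np.ndarray] = []
    for chrom, sub in frags.groupby("chrom"):
        off = offsets[chrom]
        first = sub["start"].to_numpy() // bin_size
        last = (sub["end"].to_numpy() - 1) // bin_size
        span = (last - first + 1).astype(np.int64)
        cols = np.repeat(sub["cell"].map(cell_idx).to_numpy(), span)
        rows = np.repeat(first, span) + _ranges(span) + off
        rows_acc.append(rows)
        cols_acc.append(cols)
    rows = np.concatenate(rows_acc)
    cols = np.concatenate(cols_acc)
    counts = sp.coo_matrix(
        (np.ones(rows.size, dtype=np.int64), (rows, cols)),
        shape=(n_windows, len(cells)),
    ).tocsr()
    return CountMatrix(windows, cells, counts, bin_size, target)


def _ranges(span: np.ndarray) -> np.ndarray:
    """Concatenated [0..span_i) ranges, vectorized."""
    if span.size == 0:
        return np.zeros(0, dtype=np.int64)
    total = int(span.sum())
    out = np.ones(total, dtype=np.int64)
    out[0] = 0
    ends = np.cumsum(span)[:-1]
    out[ends] = 1 - span[:-1]
    return np.cumsum(out)


def select_top_windows(m: CountMatrix, keep_frac: float = 0.40) -> CountMatrix:
    """Keep the ``floor(keep_frac * n_windows)`` windows with largest row sums.

    Ties at the cutoff rank are broken by genomic coordinate order
    (count descending, then chrom, then start) so output is deterministic.
    """
    if not 0 < keep_frac <= 1:
        raise ValueError("keep_frac must be in (0, 1]")
    n = m.counts.shape[0]
    if n == 0:
        raise ValueError("empty count matrix")
    n_keep = max(1, int(np.floor(keep_frac * n)))
    row_sums = np.asarray(m.counts.sum(axis=1)).ravel()
    # lexsort: last key is primary; position index encodes (chrom, start) order
    order = np.lexsort((np.arange(n), -row_sums))
    keep = np.sort(order[:n_keep])
    return CountMatrix(
        m.windows.iloc[keep].reset_index(drop=True),
        m.cells,
        m.counts[keep],
        m.bin_size,
        m.target,
    )


def tfidf_log(
    m: CountMatrix, scale: float = 1e4
) -> tuple[sp.csr_matrix, dict]:
    """TF-IDF scale and log-transform a window x cell count matrix.

    ``TF_ij = c_ij / colsum_j``; ``IDF_i = n_cells / n_cells_with_c_ij>0``;
    transformed value ``ln(1 + scale * TF_ij * IDF_i)``.  Windows with
    all-zero counts are dropped before computing IDF.

    Returns the transformed sparse matrix and the transform parameters
    (``idf`` vector, ``scale``, and the retained window table).
    """
    counts = m.counts.tocsr()
    colsum = np.asarray(counts.sum(axis=0)).ravel()
    zero_cells = np.flatnonzero(colsum == 0)
    if zero_cells.size:
        raise ValueError(
            "cell(s) with zero counts in selected windows: "
            f"{list(np.asarray(m.cells)[zero_cells][:5])}"
        )
    nnz_per_window = np.diff(counts.indptr)
    keep = np.flatnonzero(nnz_per_window > 0)
    counts = counts[keep]
    windows = m.windows.iloc[keep].reset_index(drop=True)
    n_cells = counts.shape[1]
    n_with = np.diff(counts.indptr)
    idf = n_cells / n_with
    tf = counts.multiply(1.0 / colsum[None, :])  # column-normalise
    x = tf.multiply(idf[:, None]).tocsr()
    x.data = np.log1p(scale * x.data)
    params = {"idf": idf, "scale": scale, "windows": windows}
    return x, params


def svd_select(
    x: sp.spmatrix | np.ndarray,
    cells: np.ndarray,
    retain_frac: float = 0.002,
) -> EmbeddingModel:
    """SVD of the transformed matrix with singular-value based retention.

    Dimensions whose singular value exceeds ``retain_frac`` times the sum of
    all singular values are retained; fewer than two such dimensions falls
    back to the top two with a warning.  Per-cell coordinates are
    ``d_j * V[:, j]`` for retained dimensions ``j``.
    """
    dense = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    if not np.all(np.isfinite(dense)):
        raise ValueError("non-finite values in transformed matrix")
    _, d, vt = np.linalg.svd(dense, full_matrices=False)
    cutoff = retain_frac * d.sum()
    retained = np.flatnonzero(d > cutoff)
    if retained.size < 2:
        warnings.warn(
            f"only {retained.size} dimension(s) pass the retention rule; "
            "falling back to the top 2"
        )
        retained = np.arange(min(2, d.size))
    coords = (d[retained][:, None] * vt[retained]).T  # cells x dims
    return EmbeddingModel(
        cells=np.asarray(cells),
        singular_values=d,
        n_retained=int(retained.size),
        coords=coords,
        retain_frac=retain_frac,
    )


def embed_2d(model: EmbeddingModel, seed: int = 0, **umap_kwargs) -> np.ndarray:
    """2-D UMAP projection of the retained SVD coordinates.

    Deterministic for a fixed seed.  Intended for visualisation; clustering
    runs on the retained SVD coordinates, not on this projection.
    """
    if model.coords.shape[0] < 3:
        raise ValueError("need at least 3 cells for a 2-D embedding")
    import umap  # deferred: numba compilation makes this import slow

    n_neighbors = min(15, model.coords.shape[0] - 1)
    reducer = umap.UMAP(
        n_components=2, random_state=seed, n_neighbors=n_neighbors, **umap_kwargs
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(model.coords)
    model.umap_coords = np.asarray(coords)
    return model.umap_coords


def cluster_kmeans(model: EmbeddingModel, k: int = 2, seed: int = 0,
                   n_init: int = 10) -> np.ndarray:
    """k-means on the retained SVD coordinates (not the 2-D projection)."""
    n_cells = model.coords.shape[0]
    if k > n_cells:
        raise ValueError(f"k={k} exceeds number of cells ({n_cells})")
    if k < 1:
        raise ValueError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(model.coords)
    model.cluster_labels = labels
    return labels


def nmi(
    true_labels, cluster_labels, average_method: str = "arithmetic"
) -> ClusterEval:
    """Normalized mutual information between a clustering and known labels.

    ``NMI = I(A;B) / mean(H(A), H(B))`` with natural logarithms (arithmetic
    normalisation by default; ``max``/``min``/``geometric`` available).
    0 when the partitions are independent, 1 when identical.
    """
    true_labels = np.asarray(true_labels)
    cluster_labels = np.asarray(cluster_labels)
    if true_labels.shape[0] != cluster_labels.shape[0]:
        raise ValueError(
            f"label length mismatch: {true_labels.shape[0]} vs {cluster_labels.shape[0]}"
        )
    value = float(
        normalized_mutual_info_score(
            true_labels, cluster_labels, average_method=average_method
        )
    )
    cont = contingency_matrix(true_labels, cluster_labels)
    cont_df = pd.DataFrame(
        cont,
        index=pd.Index(np.unique(true_labels), name="true"),
        columns=pd.Index(np.unique(cluster_labels), name="cluster"),
    )
    return ClusterEval(nmi=value, contingency=cont_df)


def integrate_targets(
    models: list[EmbeddingModel], weights: list[float] | None = None
) -> EmbeddingModel:
    """Concatenation-based multi-target integration.

    Each model's retained coordinates are standardised to unit total variance
    (so no target dominates by scale), multiplied by its weight, and
    concatenated along the feature axis.  Downstream embedding and clustering
    apply unchanged.
    """
    if not models:
        raise ValueError("no models to integrate")
    if weights is None:
        weights = [1.0] * len(models)
    if len(weights) != len(models):
        raise ValueError("one weight per model required")
    ref_cells = list(models[0].cells)
    for m in models[1:]:
        if set(m.cells) != set(ref_cells):
            only_a = sorted(set(ref_cells) - set(m.cells))[:5]
            only_b = sorted(set(m.cells) - set(ref_cells))[:5]
            raise ValueError(
                f"cell sets differ between models; e.g. only-first={only_a}, "
                f"only-other={only_b}"
            )
    blocks = []
    for m, w in zip(models, weights):
        order = pd.Index(m.cells).get_indexer(ref_cells)
        coords = m.coords[order]
        total_var = coords.var(axis=0).sum()
        if total_var > 0:
            coords = coords / np.sqrt(total_var)
        blocks.append(w * coords)
    coords = np.hstack(blocks)
    return EmbeddingModel(
        cells=np.asarray(ref_cells),
        singular_values=np.concatenate([m.singular_values for m in models]),
        n_retained=coords.shape[1],
        coords=coords,
        retain_frac=models[0].retain_frac,
    )


def lsi_pipeline(
    frags: pd.DataFrame,
    genome_sizes: dict[str, int],
    bin_size: int = 50_000,
    keep_frac: float = 0.40,
    scale: float = 1e4,
    retain_frac: float = 0.002,
) -> EmbeddingModel:
    """Convenience: bin -> top windows -> TF-IDF/log -> SVD for one target."""
    m = bin_counts(frags, genome_sizes, bin_size)
    m = select_top_windows(m, keep_frac)
    x, params = tfidf_log(m, scale)
    model = svd_select(x, m.cells, retain_frac)
    model.idf = params["idf"]
    model.window_index = params["windows"]
    return model
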