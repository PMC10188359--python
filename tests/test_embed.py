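"""Window binning, TF-IDF/SVD transforms, clustering and NMI evaluation."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from multitag import embed
from conftest import make_frags

SIZES = {"chr1": 200_000}


class TestBinCounts:
    def test_fragment_counted_in_its_window(self):
        frags = make_frags([("chr1", 100, 200, "c1", "t")])
        m = embed.bin_counts(frags, SIZES, bin_size=50_000)
        assert m.counts[0, 0] == 1
        assert m.counts.sum() == 1

    def test_boundary_spanning_fragment_counted_twice(self):
        frags = make_frags([("chr1", 49_990, 50_010, "c1", "t")])
        m = embed.bin_counts(frags, SIZES, bin_size=50_000)
        assert m.counts[0, 0] == 1 and m.counts[1, 0] == 1

    def test_empty_fragments_all_zero(self):
        from multitag import io as fio

        m = embed.bin_counts(fio.empty_fragments(), SIZES, bin_size=50_000)
        assert m.counts.shape == (4, 0)

    def test_final_partial_window_included(self):
        m = embed.bin_counts(
            make_frags([("chr1", 190_000, 190_100, "c1", "t")]),
            {"chr1": 190_500}, bin_size=50_000,
        )
        assert m.windows.iloc[-1]["end"] == 190_500
        assert m.counts[3, 0] == 1

    def test_unknown_chrom_rejected(self):
        frags = make_frags([("chrX", 0, 100, "c1", "t")])
        with pytest.raises(ValueError, match="chrX"):
            embed.bin_counts(frags, SIZES)


class TestSelectTopWindows:
    def _matrix(self, row_sums):
        n = len(row_sums)
        windows = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 100, "end": (np.arange(n) + 1) * 100}
        )
        counts = sp.csr_matrix(np.array(row_sums, dtype=np.int64)[:, None])
        return embed.CountMatrix(windows, np.array(["c1"]), counts, 100)

    def test_keeps_floor_fraction_of_top_windows(self):
        m = self._matrix(list(range(1, 11)))
        out = embed.select_top_windows(m, keep_frac=0.4)
        sums = np.asarray(out.counts.sum(axis=1)).ravel()
        assert sorted(sums) == [7, 8, 9, 10]

    def test_keep_all_is_identity(self):
        m = self._matrix([3, 1, 2])
        out = embed.select_top_windows(m, keep_frac=1.0)
        assert out.counts.shape == m.counts.shape
        pd.testing.assert_frame_equal(out.windows, m.windows)

    def test_ties_broken_by_coordinate_order(self):
        m = self._matrix([5, 5, 5, 5, 1])
        out = embed.select_top_windows(m, keep_frac=0.4)
        assert out.windows["start"].tolist() == [0, 100]

    @pytest.mark.parametrize("bad", [0.0, 1.5, -0.1])
    def test_invalid_fraction_rejected(self, bad):
        with pytest.raises(ValueError):
            embed.select_top_windows(self._matrix([1, 2]), keep_frac=bad)


class TestTfidfLog:
    def _matrix(self, arr, cells=None):
        arr = np.asarray(arr)
        n, c = arr.shape
        windows = pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * 100, "end": (np.arange(n) + 1) * 100}
        )
        cells = np.array(cells or [f"c{j}" for j in range(c)])
        return embed.CountMatrix(windows, cells, sp.csr_matrix(arr), 100)

    def test_single_cell_hand_computed_values(self):
        x, _ = embed.tfidf_log(self._matrix([[2], [8]]))
        vals = x.toarray().ravel()
        assert vals == pytest.approx([np.log(2001), np.log(8001)], rel=1e-6)
        assert vals == pytest.approx([7.6014, 8.9873], abs=1e-4)

    def test_depth_scaling_invariance(self):
        base = np.array([[2, 4], [8, 6], [1, 0]])
        doubled = base.copy()
        doubled[:, 0] *= 2  # same cell, twice the depth
        x1, _ = embed.tfidf_log(self._matrix(base))
        x2, _ = embed.tfidf_log(self._matrix(doubled))
        np.testing.assert_allclose(x1.toarray(), x2.toarray())

    def test_all_zero_window_dropped(self):
        x, params = embed.tfidf_log(self._matrix([[2, 1], [0, 0], [3, 4]]))
        assert x.shape[0] == 2
        assert params["windows"]["start"].tolist() == [0, 200]
        assert np.isfinite(x.toarray()).all()

    def test_zero_count_cell_named_in_error(self):
        with pytest.raises(ValueError, match="c1"):
            embed.tfidf_log(self._matrix([[2, 0], [1, 0]], cells=["c0", "c1"]))


class TestSvdSelect:
    def test_retention_rule_on_known_singular_values(self):
        # singular values (10, 5, 1, 0.02): cutoff = 0.002 * 16.02 = 0.03204
        rng = np.random.default_rng(0)
        q1, _ = np.linalg.qr(rng.normal(size=(6, 4)))
        q2, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        x = q1 @ np.diag([10.0, 5.0, 1.0, 0.02]) @ q2
        model = embed.svd_select(x, cells=np.array([f"c{j}" for j in range(4)]))
        assert model.n_retained == 3
        assert model.singular_values[:4] == pytest.approx([10, 5, 1, 0.02], abs=1e-8)

    def test_retain_frac_zero_keeps_all(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 4))
        model = embed.svd_select(x, np.arange(4), retain_frac=0.0)
        assert model.n_retained == 4

    def test_reconstruction_identity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(6, 5))
        u, d, vt = np.linalg.svd(x, full_matrices=False)
        np.testing.assert_allclose(u @ np.diag(d) @ vt, x, atol=1e-8)
        model = embed.svd_select(x, np.arange(5), retain_frac=0.0)
        # coords = V D must reproduce x via U: x.T = (V D) U.T
        np.testing.assert_allclose(model.coords @ u.T, x.T, atol=1e-8)

    def test_retained_count_monotone_in_retain_frac(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(20, 10))
        counts = []
        for frac in [0.0, 0.01, 0.05, 0.1, 0.2]:
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    counts.append(embed.svd_select(x, np.arange(10), retain_frac=frac).n_retained)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_fallback_to_two_dims_warns(self):
        x = np.outer([1.0, 2.0, 3.0], [1.0, 1.0, 1.0, 1.0])  # rank 1
        with pytest.warns(UserWarning, match="top 2"):
            model = embed.svd_select(x, np.arange(4), retain_frac=0.9)
        assert model.coords.shape[1] == 2


class TestClusterAndNmi:
    def _blobs(self, n=30, sep=50.0, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 3))
        b = rng.normal(sep, 1, size=(n, 3))
        coords = np.vstack([a, b])
        labels = np.array(["A"] * n + ["B"] * n)
        model = embed.EmbeddingModel(
            cells=np.array([f"c{j}" for j in range(2 * n)]),
            singular_values=np.ones(3), n_retained=3, coords=coords, retain_frac=0.002,
        )
        return model, labels

    def test_separable_clouds_recovered(self):
        model, truth = self._blobs()
        labels = embed.cluster_kmeans(model, k=2, seed=0)
        assert embed.nmi(truth, labels).nmi == pytest.approx(1.0)

    def test_k_equals_n_cells(self):
        model, _ = self._blobs(n=3)
        labels = embed.cluster_kmeans(model, k=6, seed=0)
        assert len(set(labels)) == 6

    def test_k_exceeding_cells_rejected(self):
        model, _ = self._blobs(n=2)
        with pytest.raises(ValueError):
            embed.cluster_kmeans(model, k=5)

    def test_labels_invariant_to_cell_order(self):
        model, _ = self._blobs(seed=4)
        labels = embed.cluster_kmeans(model, k=2, seed=0)
        perm = np.random.default_rng(1).permutation(len(model.cells))
        model2 = embed.EmbeddingModel(
            cells=model.cells[perm], singular_values=model.singular_values,
            n_retained=3, coords=model.coords[perm], retain_frac=0.002,
        )
        labels2 = embed.cluster_kmeans(model2, k=2, seed=0)
        # canonical renumbering: compare partitions, not raw label ids
        assert embed.nmi(labels[perm], labels2).nmi == pytest.approx(1.0)

    def test_nmi_identity(self):
        ev = embed.nmi(["a", "a", "b", "b"], ["x", "x", "y", "y"])
        assert ev.nmi == pytest.approx(1.0)

    def test_nmi_independence(self):
        ev = embed.nmi([1, 1, 2, 2], [1, 2, 1, 2])
        assert ev.nmi == pytest.approx(0.0, abs=1e-12)

    def test_nmi_hand_computed_contingency(self):
        # A=(1,1,2,2), B=(1,1,1,2): MI=0.21576 nats, H(A)=ln 2, H(B)=0.56233
        ev = embed.nmi([1, 1, 2, 2], [1, 1, 1, 2])
        assert ev.nmi == pytest.approx(0.3437, abs=1e-4)
        assert ev.contingency.to_numpy().tolist() == [[2, 0], [1, 1]]

    def test_nmi_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            embed.nmi([1, 2], [1, 2, 3])


class TestEmbed2d:
    def test_deterministic_under_seed(self):
        model, _ = TestClusterAndNmi()._blobs(n=15, seed=5)
        c1 = embed.embed_2d(model, seed=7)
        model.umap_coords = None
        c2 = embed.embed_2d(model, seed=7)
        np.testing.assert_allclose(c1, c2)

    def test_separated_types_keep_high_silhouette(self):
        from sklearn.metrics import silhouette_score

        model, truth = TestClusterAndNmi()._blobs(n=40, sep=60.0, seed=6)
        coords = embed.embed_2d(model, seed=0)
        assert silhouette_score(coords, truth) > 0.5

    def test_too_few_cells_rejected(self):
        model, _ = TestClusterAndNmi()._blobs(n=1)
        with pytest.raises(ValueError):
            embed.embed_2d(model)


class TestIntegrateTargets:
    def _model(self, coords, cells=None):
        coords = np.asarray(coords, dtype=float)
        if cells is None:
            cells = [f"c{j}" for j in range(coords.shape[0])]
        cells = np.array(cells)
        return embed.EmbeddingModel(
            cells=cells, singular_values=np.ones(coords.shape[1]),
            n_retained=coords.shape[1], coords=coords, retain_frac=0.002,
        )

    def test_single_model_identity_up_to_scale(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3))
        out = embed.integrate_targets([self._model(coords)])
        ratio = out.coords / coords
        assert np.allclose(ratio, ratio.flat[0])

    def test_two_identical_models_cluster_identically(self):
        model, truth = TestClusterAndNmi()._blobs(seed=8)
        single = embed.cluster_kmeans(model, k=2, seed=0)
        both = embed.integrate_targets([model, model])
        integrated = embed.cluster_kmeans(both, k=2, seed=0)
        assert embed.nmi(single, integrated).nmi == pytest.approx(1.0)

    def test_informative_target_dominates_noise(self):
        model, truth = TestClusterAndNmi()._blobs(n=40, sep=50.0, seed=9)
        rng = np.random.default_rng(10)
        noise = self._model(rng.normal(size=(80, 3)), cells=model.cells)
        alone = embed.nmi(truth, embed.cluster_kmeans(model, 2, seed=0)).nmi
        both = embed.integrate_targets([model, noise])
        combined = embed.nmi(truth, embed.cluster_kmeans(both, 2, seed=0)).nmi
        assert combined >= 0.9 * alone

    def test_mismatched_cells_rejected(self):
        a = self._model(np.zeros((3, 2)), cells=["x", "y", "z"])
        b = self._model(np.zeros((3, 2)), cells=["x", "y", "w"])
        with pytest.raises(ValueError, match="differ"):
            embed.integrate_targets([a, b])
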