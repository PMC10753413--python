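import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenocell import errors
from phenocell.containers import GeneMatrix
from phenocell.preprocess import (
    average_duplicate_genes,
    filter_genes_by_cell_count,
    log2_transform_bulk,
    lognormalize_sc,
    scale_and_pca,
    select_hvg,
)


def gm(genes, values, stage="raw_counts"):
    values = np.asarray(values, dtype=float)
    return GeneMatrix(genes, [f"c{j}" for j in range(values.shape[1])],
                      values, stage=stage)


class TestDuplicateAveraging:
    def test_mean_of_duplicate_rows(self):
        m = average_duplicate_genes(gm(["A", "A"], [[1, 3], [3, 5]]))
        assert m.gene_ids == ["A"]
        np.testing.assert_array_equal(m.dense(), [[2, 4]])

    def test_three_way_duplicates_and_order(self):
        m = average_duplicate_genes(
            gm(["B", "X", "B", "B"], [[0, 0], [9, 9], [3, 3], [6, 6]]))
        assert m.gene_ids == ["B", "X"]  # first-occurrence order
        np.testing.assert_array_equal(m.dense(), [[3, 3], [9, 9]])

    def test_no_duplicates_identity(self):
        src = gm(["A", "B"], [[1, 2], [3, 4]])
        out = average_duplicate_genes(src)
        assert out.gene_ids == src.gene_ids
        np.testing.assert_array_equal(out.dense(), src.dense())


class TestLog2Bulk:
    def test_anchor_values(self):
        m = log2_transform_bulk(gm(["a", "b", "c"], [[0], [1], [7]]))
        np.testing.assert_allclose(m.dense().ravel(), [0.0, 1.0, 3.0])
        assert m.stage == "log_transformed"

    def test_negative_rejected(self):
        with pytest.raises(errors.ValidationError):
            log2_transform_bulk(gm(["a"], [[-1.0]]))


class TestGeneFilter:
    def test_threshold_is_inclusive(self):
        m = gm(["lo", "edge", "hi"], [[1, 0, 0], [1, 2, 0], [1, 1, 1]])
        out = filter_genes_by_cell_count(m, 2)
        assert out.gene_ids == ["edge", "hi"]

    def test_zero_threshold_identity(self):
        m = gm(["a", "b"], [[0, 0], [1, 0]])
        assert filter_genes_by_cell_count(m, 0).gene_ids == ["a", "b"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(errors.ValidationError):
            filter_genes_by_cell_count(gm(["a"], [[1]]), -1)


class TestLogNormalize:
    def test_formula_value(self):
        # counts (1,1,2) in one cell: total 4, first entry ln(1 + 2500)
        m = lognormalize_sc(gm(["a", "b", "c"], [[1], [1], [2]]))
        np.testing.assert_allclose(m.dense()[0, 0], np.log1p(1e4 / 4.0),
                                   rtol=1e-14)
        np.testing.assert_allclose(m.dense()[2, 0], np.log1p(2e4 / 4.0),
                                   rtol=1e-14)

    def test_zero_gene_stays_zero(self):
        m = lognormalize_sc(gm(["z", "a"], [[0, 0], [5, 3]]))
        np.testing.assert_array_equal(m.dense()[0], [0.0, 0.0])

    def test_zero_total_cell_rejected(self):
        with pytest.raises(errors.ValidationError):
            lognormalize_sc(gm(["a"], [[0.0]]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(2, 20), st.integers(min_value=1, max_value=9))
    def test_invariant_to_per_cell_rescaling(self, n_genes, factor):
        rng = np.random.default_rng(n_genes * 10 + factor)
        counts = rng.poisson(3.0, size=(n_genes, 4)) + 1.0
        base = lognormalize_sc(gm([f"g{i}" for i in range(n_genes)], counts))
        scaled_counts = counts.copy()
        scaled_counts[:, 1] *= factor
        scaled = lognormalize_sc(
            gm([f"g{i}" for i in range(n_genes)], scaled_counts))
        np.testing.assert_allclose(scaled.dense(), base.dense(), rtol=1e-12)


class TestHVG:
    def test_planted_high_dispersion_genes_rank_top(self):
        rng = np.random.default_rng(11)
        n_genes, n_cells = 50, 300
        mean = 5.0
        counts = rng.poisson(mean, size=(n_genes, n_cells)).astype(float)
        hot = [3, 11, 22, 35, 48]
        for g in hot:  # negative binomial with heavy overdispersion
            r = 0.3
            counts[g] = rng.negative_binomial(r, r / (r + mean), n_cells)
        m = gm([f"g{i:02d}" for i in range(n_genes)], counts)
        top10 = select_hvg(m, 10)
        assert set(f"g{g:02d}" for g in hot) <= set(top10)

    def test_identical_genes_tie_broken_lexicographically(self):
        counts = np.array([[1, 2, 3, 4]] * 3, dtype=float)
        m = gm(["b", "a", "c"], counts)
        assert select_hvg(m, 3) == ["a", "b", "c"]

    def test_nhvg_clamped_with_warning(self, caplog):
        m = gm(["a", "b"], np.random.default_rng(0).poisson(4, (2, 10)) + 1.0)
        assert len(select_hvg(m, 100)) == 2


class TestScalePCA:
    def _normalized(self, values, genes=None):
        genes = genes or [f"g{i}" for i in range(values.shape[0])]
        return GeneMatrix(genes, [f"c{j}" for j in range(values.shape[1])],
                          values, stage="normalized")

    def test_first_pc_aligns_with_dominant_direction(self):
        rng = np.random.default_rng(5)
        n_genes, n_cells = 12, 20
        direction = rng.normal(size=n_genes)
        direction /= np.linalg.norm(direction)
        scores = rng.normal(scale=5.0, size=n_cells)
        data = np.outer(direction, scores) + rng.normal(
            scale=0.05, size=(n_genes, n_cells))
        m = self._normalized(data)
        emb = scale_and_pca(m, m.gene_ids, 3)
        # oracle: full eigendecomposition of the scaled covariance
        z = (data - data.mean(1, keepdims=True)) / data.std(1, ddof=1,
                                                            keepdims=True)
        cov = np.cov(z)
        w, v = np.linalg.eigh(cov)
        lead = v[:, -1]
        # compare cell scores along the lead direction
        scores_oracle = z.T @ lead
        cos = np.corrcoef(scores_oracle, emb.coordinates[:, 0])[0, 1]
        assert abs(cos) > 0.99

    def test_explained_variance_non_increasing_and_duplicate_cells(self):
        rng = np.random.default_rng(6)
        data = rng.normal(size=(15, 25))
        data[:, 1] = data[:, 0]  # two identical cells
        m = self._normalized(data)
        emb = scale_and_pca(m, m.gene_ids, 5)
        assert np.all(np.diff(emb.explained_variance) <= 1e-9)
        np.testing.assert_allclose(emb.coordinates[0], emb.coordinates[1],
                                   atol=1e-9)

    def test_low_rank_distances_preserved(self):
        rng = np.random.default_rng(7)
        n_pcs = 4
        latent = rng.normal(size=(30, n_pcs))
        load = rng.normal(size=(n_pcs, 18))
        data = (latent @ load).T  # genes x cells of true rank n_pcs
        m = self._normalized(data)
        emb = scale_and_pca(m, m.gene_ids, n_pcs)
        z = (data - data.mean(1, keepdims=True)) / data.std(1, ddof=1,
                                                            keepdims=True)
        from scipy.spatial.distance import pdist

        d_full = pdist(z.T)
        d_emb = pdist(emb.coordinates)
        mask = d_full > 1e-9
        assert np.max(np.abs(d_emb[mask] - d_full[mask]) / d_full[mask]) < 0.05

    def test_more_pcs_than_cells_rejected(self):
        m = self._normalized(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(errors.ValidationError):
            scale_and_pca(m, m.gene_ids, 4)


def test_stage_tags_enforce_pipeline_order(toy_bulk):
    logged = log2_transform_bulk(toy_bulk)
    with pytest.raises(errors.StageError):
        log2_transform_bulk(logged)  # cannot log twice
    with pytest.raises(errors.StageError):
        lognormalize_sc(logged)  # normalization needs raw counts
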