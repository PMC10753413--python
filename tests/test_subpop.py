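import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from phenocell import errors
from phenocell.containers import GeneMatrix
from phenocell.sgl import SGLFit
from phenocell.subpop import (
    benjamini_hochberg,
    classify_cells,
    differential_expression,
    summarize_assignment,
)


def make_fit(coefs, groups=None):
    coefs = np.asarray(coefs, dtype=float)
    groups = (np.zeros(len(coefs), dtype=int) if groups is None
              else np.asarray(groups))
    return SGLFit(cell_ids=[f"c{i}" for i in range(len(coefs))],
                  group_labels=groups, coef=coefs, intercept=0.0,
                  alpha=0.5, lam=0.1)


class TestClassify:
    def test_sign_rule(self):
        assign = classify_cells(make_fit([0.5, -0.2, 0.0]))
        assert list(assign.labels) == ["positive", "negative", "background"]

    def test_all_zero_is_all_background(self):
        assign = classify_cells(make_fit([0.0, 0.0]))
        assert set(assign.labels) == {"background"}

    def test_numerical_zero_threshold(self):
        assign = classify_cells(make_fit([1e-15, 0.3]))
        assert list(assign.labels) == ["background", "positive"]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-2, 2, allow_nan=False), min_size=1,
                    max_size=40))
    def test_labels_partition_cells(self, coefs):
        assign = classify_cells(make_fit(coefs))
        counts = {lab: int(np.sum(assign.labels == lab))
                  for lab in ("positive", "negative", "background")}
        assert sum(counts.values()) == len(coefs)


class TestSummaries:
    def test_positives_in_one_group(self):
        assign = classify_cells(
            make_fit([1.0, 1, 1, 1, -1], groups=[1, 1, 1, 1, 0]))
        table = summarize_assignment(assign, by="group")
        assert table.loc["group_2", "positive_count"] == 4
        assert table.loc["group_2", "positive_pct"] == pytest.approx(100.0)

    def test_annotation_split(self):
        fit = make_fit([1.0, 1, 1, 1])
        assign = classify_cells(fit, annotations=["T", "T", "T", "B"])
        table = summarize_assignment(assign, by="annotation")
        assert table.loc["T", "positive_pct"] == pytest.approx(75.0)
        assert table.loc["B", "positive_pct"] == pytest.approx(25.0)

    def test_zero_positive_cells_not_an_error(self):
        assign = classify_cells(make_fit([-1.0, 0.0]))
        table = summarize_assignment(assign, by="group")
        assert table["positive_count"].sum() == 0
        assert table["positive_pct"].sum() == 0.0

    def test_missing_annotation_rejected(self):
        assign = classify_cells(make_fit([1.0]))
        with pytest.raises(errors.ValidationError):
            summarize_assignment(assign, by="annotation")


def expr_matrix(values, stage="normalized"):
    values = np.asarray(values, dtype=float)
    return GeneMatrix([f"g{i}" for i in range(values.shape[0])],
                      [f"c{j}" for j in range(values.shape[1])],
                      values, stage=stage)


class TestDifferentialExpression:
    def test_identical_groups_nothing_passes(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(20, 5))
        expr = expr_matrix(np.hstack([block, block]))
        res = differential_expression(
            expr, [f"c{j}" for j in range(5)],
            [f"c{j}" for j in range(5, 10)], logfc_threshold=0.1,
            sig_threshold=0.05)
        assert res.passing.empty

    def test_vacuous_filter_passes_everything(self):
        rng = np.random.default_rng(1)
        expr = expr_matrix(rng.normal(size=(30, 12)))
        res = differential_expression(
            expr, [f"c{j}" for j in range(6)],
            [f"c{j}" for j in range(6, 12)], logfc_threshold=0.0,
            sig_threshold=1.0, sig_on="pvalue")
        assert res.passing.shape[0] == 30

    def test_planted_shift_detected_reliably(self):
        hits = 0
        for trial in range(40):
            rng = np.random.default_rng(100 + trial)
            data = rng.normal(size=(100, 40))
            data[17, :20] += np.log2(10.0)  # 10x shift in group A
            expr = expr_matrix(data)
            res = differential_expression(
                expr, [f"c{j}" for j in range(20)],
                [f"c{j}" for j in range(20, 40)], logfc_threshold=1.0,
                sig_threshold=0.05, sig_on="fdr")
            if "g17" in set(res.passing["gene"]):
                hits += 1
        assert hits >= 38  # >= 95% of seeded trials

    def test_welch_t_and_bh_match_reference_formulas(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        data = rng.normal(size=(25, 14))
        a_cols, b_cols = list(range(8)), list(range(8, 14))
        expr = expr_matrix(data)
        res = differential_expression(
            expr, [f"c{j}" for j in a_cols], [f"c{j}" for j in b_cols])
        t_ref, p_ref = stats.ttest_ind(data[:, a_cols], data[:, b_cols],
                                       axis=1, equal_var=False)
        np.testing.assert_allclose(res.table["t_stat"], t_ref, rtol=1e-12)
        np.testing.assert_allclose(res.table["p_value"], p_ref, rtol=1e-12)
        np.testing.assert_allclose(res.table["fdr"],
                                   oracles.bh_adjusted(p_ref), rtol=1e-12)

    def test_singleton_group_rejected(self):
        expr = expr_matrix(np.ones((4, 5)))
        with pytest.raises(errors.DegenerateGroupError):
            differential_expression(expr, ["c0"], ["c1", "c2"])

    def test_overlapping_groups_rejected(self):
        expr = expr_matrix(np.ones((4, 5)))
        with pytest.raises(errors.ValidationError):
            differential_expression(expr, ["c0", "c1"], ["c1", "c2"])


class TestBenjaminiHochberg:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(1, 300), st.integers(0, 10_000))
    def test_rejection_set_matches_stepup_oracle(self, m, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(m) ** rng.uniform(0.3, 3.0)
        adj = benjamini_hochberg(p)
        for q in (0.01, 0.05, 0.2):
            np.testing.assert_array_equal(
                adj <= q, oracles.bh_rejections(p, q))

    def test_adjusted_values_match_oracle(self):
        rng = np.random.default_rng(7)
        p = rng.random(500)
        np.testing.assert_allclose(benjamini_hochberg(p),
                                   oracles.bh_adjusted(p), rtol=1e-12)
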