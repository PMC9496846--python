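import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ufgpanel.core_io import ExpressionMatrix
from ufgpanel.diffexpr import (
    ModerationHyperparams,
    bh_adjust,
    count_significant,
    diffexpr_table,
    estimate_moderation,
    moderated_t_test,
    quartile_log2fc,
    zscore_matrix,
)
from ufgpanel.potency import QuartileAssignment


def two_group_assignment(n1: int, n2: int, middle: int = 0) -> QuartileAssignment:
    """Assignment whose top/bottom are the first n1 / last n2 lines."""
    lines = tuple(f"L{i:03d}" for i in range(n1 + middle + n2))
    q = min(n1, n2)
    assert n1 == n2, "helper assumes equal quartiles"
    return QuartileAssignment(drug="d", ordering=lines, q=n1)


def matrix(values: np.ndarray) -> ExpressionMatrix:
    genes = [f"g{i}" for i in range(values.shape[0])]
    lines = [f"L{i:03d}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=lines))


class TestLog2FoldChange:
    def test_hand_arithmetic(self):
        expr = matrix(np.array([[3.0, 5.0, 1.0, 3.0]]))
        a = two_group_assignment(2, 2)
        assert quartile_log2fc(expr, a, "g0") == pytest.approx(2.0)

    def test_equal_means_give_zero(self):
        expr = matrix(np.array([[2.0, 4.0, 1.0, 5.0]]))
        a = two_group_assignment(2, 2)
        assert quartile_log2fc(expr, a, "g0") == pytest.approx(0.0)

    def test_absent_gene_is_error(self):
        expr = matrix(np.zeros((1, 4)) + 1.0)
        a = two_group_assignment(2, 2)
        with pytest.raises(KeyError):
            quartile_log2fc(expr, a, "nope")


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self):
        rng = np.random.default_rng(3)
        expr = matrix(rng.normal(size=(50, 20)))
        a = two_group_assignment(10, 10)
        res = moderated_t_test(expr, a, ModerationHyperparams(0.0, 1.0))
        x = expr.data.iloc[:, :10].to_numpy()
        y = expr.data.iloc[:, 10:].to_numpy()
        # note: top/bottom columns are sorted by line name = original order here
        ref_t, ref_p = stats.ttest_ind(x, y, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"].to_numpy(), ref_t, atol=1e-10)
        np.testing.assert_allclose(res["p"].to_numpy(), ref_p, atol=1e-10)

    def test_constant_gene_finite_with_moderation(self):
        values = np.vstack(
            [np.r_[np.ones(5) * 4, np.ones(5)], np.random.default_rng(0).normal(size=(30, 10))]
        )
        expr = matrix(values)
        a = two_group_assignment(5, 5)
        res = moderated_t_test(expr, a, "auto")
        assert np.isfinite(res.loc["g0", "t"])
        assert 0 < res.loc["g0", "p"] < 0.05

    def test_constant_gene_undefined_without_moderation(self):
        values = np.vstack([np.r_[np.ones(5) * 2, np.ones(5)]])
        expr = matrix(values)
        a = two_group_assignment(5, 5)
        res = moderated_t_test(expr, a, "off")
        assert np.isnan(res.loc["g0", "p"])

    def test_identical_true_variance_agrees_with_ordinary_t(self):
        # all genes share one variance: shrinkage leaves t nearly unchanged
        rng = np.random.default_rng(11)
        expr = matrix(rng.normal(0, 0.5, size=(2000, 24)))
        a = two_group_assignment(12, 12)
        mod = moderated_t_test(expr, a, "auto")
        ord_ = moderated_t_test(expr, a, "off")
        resid = np.abs(mod["t"] - ord_["t"])
        assert np.median(resid) < 0.25
        assert np.corrcoef(mod["t"], ord_["t"])[0, 1] > 0.98

    def test_swapping_quartiles_negates_t_keeps_p(self):
        rng = np.random.default_rng(4)
        expr = matrix(rng.normal(size=(40, 12)))
        lines = tuple(expr.lines)
        fwd = QuartileAssignment(drug="d", ordering=lines, q=6)
        rev = QuartileAssignment(drug="d", ordering=lines[::-1], q=6)
        a = moderated_t_test(expr, fwd, "off")
        b = moderated_t_test(expr, rev, "off")
        np.testing.assert_allclose(a["t"], -b["t"], atol=1e-12)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)
        np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)

    def test_type_I_error_calibrated_under_null(self):
        rng = np.random.default_rng(9)
        expr = matrix(rng.normal(size=(4000, 50)))
        a = two_group_assignment(25, 25)
        res = moderated_t_test(expr, a, "auto")
        frac = float((res["p"] < 0.05).mean())
        # binomial 4-sigma band around 0.05 (correlated tests are iid here)
        assert abs(frac - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 4000)

    def test_prior_estimation_recovers_generating_hyperparams(self):
        rng = np.random.default_rng(21)
        d0_true, s0_true, d = 8.0, 0.04, 18
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, 20000)
        s2 = sigma2 * rng.chisquare(d, 20000) / d
        est = estimate_moderation(s2, d)
        assert est.d0 == pytest.approx(d0_true, rel=0.15)
        assert est.s0_sq == pytest.approx(s0_true, rel=0.05)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestLimmaOracle:
    """Independent cross-check against the Bioconductor limma implementation."""

    R_CODE = """
    suppressMessages(library(limma))
    x <- as.matrix(read.delim("{mat}", header=FALSE))
    n <- ncol(x)/2
    design <- cbind(Intercept=1, Group=c(rep(1,n), rep(0,n)))
    fit <- eBayes(lmFit(x, design))
    out <- data.frame(t=fit$t[,"Group"], p=fit$p.value[,"Group"])
    write.table(out, "{out}", sep="\\t", row.names=FALSE, quote=FALSE)
    """

    def test_matches_ebayes_moderated_t(self, tmp_path):
        rng = np.random.default_rng(5)
        n1, ng = 10, 300
        sigma2 = 0.05 * 8 / rng.chisquare(8, ng)
        x = rng.normal(0, np.sqrt(sigma2)[:, None], (ng, 2 * n1))
        x[:10, :n1] += 1.0
        mat = tmp_path / "mat.tsv"
        out = tmp_path / "limma.tsv"
        pd.DataFrame(x).to_csv(mat, sep="\t", index=False, header=False)
        script = tmp_path / "check.R"
        script.write_text(self.R_CODE.format(mat=mat, out=out))
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)

        expr = matrix(x)
        a = two_group_assignment(n1, n1)
        mine = moderated_t_test(expr, a, "auto")
        limma = pd.read_csv(out, sep="\t")
        np.testing.assert_allclose(mine["t"].to_numpy(), limma["t"].to_numpy(), atol=1e-8)
        np.testing.assert_allclose(mine["p"].to_numpy(), limma["p"].to_numpy(), atol=1e-8)


def bh_step_up_oracle(p):
    """Literal step-up definition: q_(i) = min over j>=i of p_(j)*m/j, capped."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[order[i]] = min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0)
    return q


class TestBHAdjust:
    def test_single_value_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_oracle_on_small_grid(self):
        grid = [0.001, 0.01, 0.05, 0.2, 0.5, 1.0]
        for n in range(1, 5):
            for combo in itertools.combinations_with_replacement(grid, n):
                np.testing.assert_allclose(
                    bh_adjust(list(combo)), bh_step_up_oracle(combo), atol=1e-12
                )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=6))
    def test_matches_oracle_and_is_monotone(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_step_up_oracle(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestTableAndCounts:
    def test_counts_partition_and_thresholds(self):
        rng = np.random.default_rng(2)
        expr = matrix(rng.normal(size=(100, 20)))
        a = two_group_assignment(10, 10)
        table = diffexpr_table(expr, a, "auto")
        assert set(table.columns) == {"gene", "drug", "log2fc", "t", "p", "q", "direction"}
        n, up, down = count_significant(table, "d", 0.05)
        assert n == up + down
        assert n == int((table["p"] < 0.05).sum())

    def test_empty_table(self):
        empty = pd.DataFrame(columns=["gene", "drug", "log2fc", "t", "p", "q", "direction"])
        assert count_significant(empty, "d", 0.05) == (0, 0, 0)

    def test_bad_alpha_is_error(self):
        empty = pd.DataFrame(columns=["gene", "drug", "p", "direction"])
        with pytest.raises(ValueError):
            count_significant(empty, "d", 1.5)


class TestZScore:
    def test_rows_standardized(self):
        rng = np.random.default_rng(6)
        expr = matrix(rng.normal(3, 2, size=(10, 30)))
        z = zscore_matrix(expr)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(1, 12))
        z1 = zscore_matrix(matrix(base))
        z2 = zscore_matrix(matrix(3.5 * base + 7))
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-10)

    def test_constant_gene_is_error(self):
        expr = matrix(np.ones((2, 5)) * np.array([[1.0], [2.0]]))
        with pytest.raises(ValueError, match="g0"):
            zscore_matrix(expr)
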