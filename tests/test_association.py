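from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from metascreener import (correlation_test, differential_test, moderated_ttest,
                          two_to_one)
from metascreener.association import (COR_TESTS, DIFF_TESTS,
                                      correlation_stats_matrix,
                                      differential_stats_matrix)

MASK_33 = np.array([True, True, True, False, False, False])


class TestTwoToOne:
    @pytest.mark.parametrize("p,direction,p_act,p_inh", [
        (0.04, +1, 0.02, 0.98),
        (1.0, +1, 0.5, 0.5),
        (1.0, -1, 0.5, 0.5),
        (0.04, -1, 0.98, 0.02),
        (0.5, 0, 0.25, 0.75),     # ties routed as non-negative
    ])
    def test_halving_and_mirror_rules(self, p, direction, p_act, p_inh):
        dp = two_to_one(p, direction)
        assert dp.p_act == pytest.approx(p_act)
        assert dp.p_inh == pytest.approx(p_inh)

    @settings(max_examples=200, deadline=None)
    @given(p=st.floats(1e-12, 1.0), direction=st.sampled_from([-1, 0, 1]))
    def test_complement_identity(self, p, direction):
        dp = two_to_one(p, direction)
        assert dp.p_act + dp.p_inh == pytest.approx(1.0, abs=1e-12)
        assert 0.0 < dp.p_act < 1.0


class TestDifferential:
    def test_welch_t_example(self):
        res = differential_test(np.array([1, 2, 3, 4, 5, 6.0]), MASK_33, "ttest")
        assert res.effect == pytest.approx(-3.0)
        assert abs(res.statistic) == pytest.approx(3.674, abs=1e-3)
        assert res.p_two == pytest.approx(0.0213, abs=2e-3)
        assert res.direction == -1

    def test_wilcoxon_exact_small_n(self):
        res = differential_test(np.array([1, 2, 3, 4, 5, 6.0]), MASK_33, "wilcoxon")
        assert res.p_two == pytest.approx(0.1)   # 2/20 rank assignments as extreme
        assert res.direction == -1

    def test_permutation_matches_exhaustive_oracle(self):
        x = np.array([0.3, 1.2, 0.7, 2.5, 3.1, 2.2])
        res = differential_test(x, MASK_33, "permutation", n_perm=1000, seed=0)
        obs = x[:3].mean() - x[3:].mean()
        null = [x[list(idx)].mean() - np.delete(x, list(idx)).mean()
                for idx in combinations(range(6), 3)]
        p_oracle = np.mean([abs(t) >= abs(obs) - 1e-12 for t in null])
        assert res.p_two == pytest.approx(p_oracle)

    @pytest.mark.parametrize("method", DIFF_TESTS)
    def test_identical_groups_null(self, method):
        x = np.array([1.0, 2, 3, 1, 2, 3])
        res = differential_test(x, MASK_33, method, seed=0)
        assert res.direction == 0
        assert res.p_two == pytest.approx(1.0)

    @pytest.mark.parametrize("method", DIFF_TESTS)
    def test_label_swap_flips_direction_and_swaps_sides(self, method):
        rng = np.random.default_rng(8)
        x = rng.normal(size=14)
        x[:7] += 1.0
        mask = np.array([True] * 7 + [False] * 7)
        a = differential_test(x, mask, method, seed=1)
        b = differential_test(x, ~mask, method, seed=1)
        assert b.direction == -a.direction
        assert b.p_two == pytest.approx(a.p_two, rel=1e-9)
        da, db = two_to_one(a.p_two, a.direction), two_to_one(b.p_two, b.direction)
        assert db.p_act == pytest.approx(da.p_inh)

    def test_too_small_class_rejected(self):
        with pytest.raises(ValueError, match="needs >=2"):
            differential_test(np.arange(5.0), np.array([True] + [False] * 4), "ttest")

    def test_matrix_and_scalar_paths_agree(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 20))
        mask = np.array([True] * 10 + [False] * 10)
        for method in ["ttest", "anova", "kruskal"]:
            d = differential_stats_matrix(X, mask, method)
            for i in range(6):
                r = differential_test(X[i], mask, method)
                assert r.p_two == pytest.approx(float(d["p_two"][i]), rel=1e-9)


class TestModeratedT:
    def test_matches_bioconductor_limma(self, tmp_path):
        """Independent oracle: lmFit + eBayes from the R limma package."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(7)
        X = rng.normal(5, 1, size=(40, 12))
        X[:5, :6] += 1.5
        np.savetxt(tmp_path / "m.tsv", X, delimiter="\t",
                   header="\t".join(f"s{j}" for j in range(12)), comments="")
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"x <- as.matrix(read.delim('{tmp_path}/m.tsv'))\n"
            "design <- cbind(Intercept=1, grp=c(rep(1,6), rep(0,6)))\n"
            "fit <- eBayes(lmFit(x, design))\n"
            "out <- cbind(fit$t[,'grp'], fit$p.value[,'grp'])\n"
            f"write.table(out, '{tmp_path}/out.tsv', sep='\\t', col.names=FALSE, row.names=FALSE)\n")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True, text=True)
        if proc.returncode != 0:
            pytest.skip(f"R limma oracle failed to run: {proc.stderr[-200:]}")
        oracle = np.loadtxt(tmp_path / "out.tsv")
        mine = moderated_ttest(X, np.array([True] * 6 + [False] * 6))
        assert np.abs(mine["statistic"] - oracle[:, 0]).max() < 0.1
        assert np.abs(mine["p_two"] - oracle[:, 1]).max() < 0.01

    def test_single_row_falls_back_to_ordinary_t(self):
        x = np.array([[1, 2, 3, 4, 5, 6.0]])
        d = moderated_ttest(x, MASK_33)
        t, p = stats.ttest_ind(x[0, :3], x[0, 3:], equal_var=True)
        assert d["statistic"][0] == pytest.approx(t)
        assert d["p_two"][0] == pytest.approx(p)


class TestCorrelation:
    def test_perfect_linearity(self):
        res = correlation_test(np.array([1, 2, 3, 4, 5.0]),
                               np.array([2, 4, 6, 8, 10.0]), "pearson")
        assert res.effect == pytest.approx(1.0)
        assert res.direction == 1

    def test_kendall_perfect_reversal(self):
        res = correlation_test(np.array([1, 2, 3, 4, 5.0]),
                               np.array([5, 4, 3, 2, 1.0]), "kendall")
        assert res.effect == pytest.approx(-1.0)
        assert res.direction == -1

    def test_blomqvist_against_quadrant_count_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=9)
        y = x + rng.normal(scale=0.8, size=9)
        res = correlation_test(x, y, "blomqvist")
        a, b = x - np.median(x), y - np.median(y)
        nc = int(((a * b) > 0).sum())
        nd = int(((a * b) < 0).sum())
        assert res.effect == pytest.approx((nc - nd) / (nc + nd))
        assert res.p_two == pytest.approx(stats.binomtest(nc, nc + nd, 0.5).pvalue)

    @pytest.mark.parametrize("method", COR_TESTS)
    def test_state_negation_flips_direction(self, method):
        rng = np.random.default_rng(5)
        x = rng.normal(size=24)
        y = 0.7 * x + rng.normal(scale=0.5, size=24)
        a = correlation_test(x, y, method, n_perm=200, seed=3)
        b = correlation_test(x, -y, method, n_perm=200, seed=3)
        assert b.direction == -a.direction
        assert b.p_two == pytest.approx(a.p_two, rel=1e-6)
        da, db = two_to_one(a.p_two, a.direction), two_to_one(b.p_two, b.direction)
        assert db.p_act == pytest.approx(da.p_inh, rel=1e-6)

    @pytest.mark.parametrize("bad", [np.full(8, 2.0)])
    def test_constant_input_rejected(self, bad):
        with pytest.raises(ValueError, match="constant"):
            correlation_test(bad, np.arange(8.0), "pearson")

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="n >= 5"):
            correlation_test(np.arange(4.0), np.arange(4.0), "pearson")

    def test_lm_slope_recovers_generating_coefficient(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=200)
        y = 2.5 * x + rng.normal(scale=0.2, size=200)
        res = correlation_test(x, y, "lm")
        assert res.effect == pytest.approx(2.5, abs=0.1)


class TestNullCalibration:
    """Two-tailed p-values should be uniform under the null."""

    @pytest.mark.parametrize("method", ["ttest", "wilcoxon", "kruskal", "limma"])
    def test_differential_null_uniform(self, method):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(2000, 40))
        mask = np.array([True] * 20 + [False] * 20)
        d = differential_stats_matrix(X, mask, method)
        stat, p = stats.kstest(d["p_two"], "uniform")
        assert p > 0.001

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_correlation_null_uniform(self, method):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(2000, 30))
        y = rng.normal(size=30)
        d = correlation_stats_matrix(X, y, method)
        stat, p = stats.kstest(d["p_two"], "uniform")
        assert p > 0.001
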