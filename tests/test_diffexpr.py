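"""Normalization, summarization, moderated t, BH, splicing gate, UPGMA."""

import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats, special

from retinomature.diffexpr import (
    bh_adjust, fit_variance_prior, hierarchical_cluster_samples,
    low_signal_filter, median_polish, moderated_t_test, quantile_normalize,
    select_de, splicing_index, splicing_index_aggregate, summarize_probe_sets,
    ShrinkageEstimate,
)


def median_polish_oracle(x, max_iter=10, tol=1e-6):
    """Independently coded two-way median polish (scalar loops)."""
    x = [row[:] for row in x]
    nr, nc = len(x), len(x[0])
    overall, re_, ce = 0.0, [0.0] * nr, [0.0] * nc
    prev = sum(abs(v) for row in x for v in row)
    for _ in range(max_iter):
        for i in range(nr):
            med = float(np.median(x[i]))
            re_[i] += med
            for j in range(nc):
                x[i][j] -= med
        med = float(np.median(re_))
        overall += med
        re_ = [v - med for v in re_]
        for j in range(nc):
            med = float(np.median([x[i][j] for i in range(nr)]))
            ce[j] += med
            for i in range(nr):
                x[i][j] -= med
        med = float(np.median(ce))
        overall += med
        ce = [v - med for v in ce]
        total = sum(abs(v) for row in x for v in row)
        if abs(prev - total) < tol * max(prev, 1.0):
            break
        prev = total
    return overall, re_, ce


class TestQuantileNormalize:
    def test_two_column_worked_example(self):
        # log2 values [1,2,3] and [4,5,6] -> both columns [2.5, 3.5, 4.5]
        df = pd.DataFrame({"a": [2.0, 4.0, 8.0], "b": [16.0, 32.0, 64.0]})
        out = quantile_normalize(df)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_identical_distributions_unchanged(self, rng):
        col = 2.0 ** rng.uniform(4, 10, 50)
        df = pd.DataFrame({"a": col, "b": rng.permutation(col)})
        out = quantile_normalize(df)
        assert np.allclose(np.sort(out["a"]), np.sort(np.log2(col)))

    def test_sorted_columns_identical_and_idempotent(self, rng):
        df = pd.DataFrame(2.0 ** rng.uniform(2, 12, size=(40, 5)))
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            assert np.allclose(np.sort(out.iloc[:, j]), ref, atol=1e-12)
        again = quantile_normalize(out, assume_log2=True)
        assert np.allclose(again.to_numpy(), out.to_numpy(), atol=1e-12)

    def test_rank_order_preserved(self, rng):
        df = pd.DataFrame(2.0 ** rng.uniform(2, 12, size=(30, 3)))
        out = quantile_normalize(df)
        for j in range(3):
            assert (np.argsort(out.iloc[:, j].to_numpy())
                    == np.argsort(df.iloc[:, j].to_numpy())).all()

    def test_ties_get_mean_of_destination_quantiles(self):
        df = pd.DataFrame({"a": [2.0, 2.0, 8.0], "b": [2.0, 4.0, 8.0]})
        out = quantile_normalize(df)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_nonpositive_intensity_names_cell(self):
        df = pd.DataFrame({"a": [1.0, -2.0]}, index=["r1", "r2"])
        with pytest.raises(ValueError, match="r2"):
            quantile_normalize(df)


class TestMedianPolish:
    def test_identical_probe_rows_recovered(self):
        v = np.array([3.0, 5.0, 4.0, 6.0])
        m = np.tile(v, (5, 1))
        overall, re_, ce, _ = median_polish(m)
        assert np.allclose(overall + ce, v)

    def test_probe_offsets_absorbed_into_row_effects(self, rng):
        v = rng.normal(8, 1, size=6)
        offsets = rng.normal(0, 2, size=7)
        m = v[None, :] + offsets[:, None]
        overall, _, ce, _ = median_polish(m)
        assert np.allclose(overall + ce - (overall + ce).mean() + v.mean(), v,
                           atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.normal(0, 1, size=(5, 4))
        overall, re_, ce, _ = median_polish(m)
        o2, r2, c2 = median_polish_oracle(m.tolist())
        assert math.isclose(overall, o2, abs_tol=1e-6)
        assert np.allclose(ce, c2, atol=1e-6)
        assert np.allclose(re_, r2, atol=1e-6)

    def test_summarize_probe_sets(self, rng):
        v = rng.normal(8, 1, size=4)
        m = pd.DataFrame(np.tile(v, (3, 1)), index=["p1", "p2", "p3"],
                         columns=list("abcd"))
        out = summarize_probe_sets(m, {"PS1": ["p1", "p2", "p3"]})
        assert np.allclose(out.loc["PS1"], v)
        with pytest.raises(RuntimeError):
            summarize_probe_sets(m, {"PS1": []})


class TestLowSignalFilter:
    def test_threshold_semantics(self):
        df = pd.DataFrame({
            "s1": [5.99, 6.2, 6.0], "s2": [5.5, 4.0, 5.0]},
            index=["all_low", "one_high", "max_exactly_6"])
        kept, removed = low_signal_filter(df, threshold=6.0)
        assert removed == ["all_low"]
        assert set(kept.index) == {"one_high", "max_exactly_6"}


class TestVariancePrior:
    def test_constant_variances_give_infinite_d0(self):
        d = 4
        est = fit_variance_prior(np.full(50, 0.5), d)
        assert math.isinf(est.d0)
        expected = 0.5 * math.exp(-special.digamma(d / 2) + math.log(d / 2))
        assert math.isclose(est.s0_sq, expected, rel_tol=1e-12)

    def test_parameter_recovery_simulation(self):
        rng = np.random.default_rng(5)
        d0, s0, d, n = 4.0, 0.04, 4, 5000
        sig2 = d0 * s0 / rng.chisquare(d0, n)
        s2 = sig2 * rng.chisquare(d, n) / d
        est = fit_variance_prior(s2, d)
        assert abs(est.d0 - d0) / d0 < 0.15
        assert abs(est.s0_sq - s0) / s0 < 0.15

    def test_dispersed_variances_give_finite_d0(self):
        est = fit_variance_prior(np.array([0.01, 10.0, 0.02, 5.0]), 4)
        assert 0 < est.d0 < math.inf

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_variance_prior(np.zeros(10), 4)


class TestModeratedT:
    def test_worked_pooled_t_example(self):
        # y3=(1,2,3), y5=(3,4,5): log2fc=2, pooled s2=1, t=2.449, p~=0.0705
        df = pd.DataFrame([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]],
                          columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        res = moderated_t_test(df, ["b1", "b2", "b3"], ["a1", "a2", "a3"],
                               prior=ShrinkageEstimate(d0=1e-300, s0_sq=1.0))
        # d0=0 limit: ordinary pooled two-sample t
        res0 = moderated_t_test(df, ["b1", "b2", "b3"], ["a1", "a2", "a3"],
                                prior=_zero_prior())
        assert math.isclose(res0["log2fc"].iloc[0], 2.0)
        assert math.isclose(res0["s_g_sq"].iloc[0], 1.0)
        assert math.isclose(res0["t_mod"].iloc[0], 2.0 / math.sqrt(2.0 / 3.0),
                            rel_tol=1e-12)
        assert res0["df_total"].iloc[0] == 4
        assert math.isclose(res0["p"].iloc[0], 0.07048399691021,
                            rel_tol=1e-9)
        assert np.allclose(res["t_mod"], res0["t_mod"], rtol=1e-6)

    def test_d0_zero_equals_scipy_pooled_t(self, rng):
        m = pd.DataFrame(rng.normal(8, 1, size=(30, 6)),
                         columns=list("abcdef"))
        res = moderated_t_test(m, list("abc"), list("def"), prior=_zero_prior())
        t_ref, p_ref = stats.ttest_ind(m[list("abc")], m[list("def")], axis=1)
        assert np.allclose(res["t_mod"], t_ref, atol=1e-10)
        assert np.allclose(res["p"], p_ref, atol=1e-10)

    def test_equal_means_give_t_zero_p_one(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0, 2.0, 1.0, 3.0]],
                          columns=list("abcdef"))
        res = moderated_t_test(df, list("abc"), list("def"), prior=_zero_prior())
        assert res["t_mod"].iloc[0] == 0.0 and res["p"].iloc[0] == 1.0

    def test_group_swap_flips_sign(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(20, 6)), columns=list("abcdef"))
        r1 = moderated_t_test(m, list("abc"), list("def"))
        r2 = moderated_t_test(m, list("def"), list("abc"))
        assert np.allclose(r1["t_mod"], -r2["t_mod"])
        assert np.allclose(r1["p"], r2["p"])

    def test_requires_two_replicates(self):
        df = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
        with pytest.raises(ValueError):
            moderated_t_test(df, ["a"], ["b", "c"])

    def test_matches_limma_reference(self, tmp_path):
        """Full eBayes chain vs the Bioconductor reference on one dataset."""
        rng = np.random.default_rng(42)
        m = rng.normal(8, 1, size=(200, 1)) + rng.normal(0, 0.4, size=(200, 6))
        m[:20, 3:] += 1.2
        df = pd.DataFrame(m, index=[f"r{i}" for i in range(200)],
                          columns=list("abcdef"))
        mat = tmp_path / "mat.tsv"
        df.to_csv(mat, sep="\t")
        script = tmp_path / "cmp.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'm <- as.matrix(read.delim("{mat}", row.names=1))\n'
            'design <- cbind(Intercept=1, g=c(0,0,0,1,1,1))\n'
            'fit <- eBayes(lmFit(m, design))\n'
            'out <- data.frame(t=fit$t[, "g"], p=fit$p.value[, "g"],\n'
            '                  d0=fit$df.prior, s0=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)\n')
        proc = subprocess.run(["Rscript", str(script)], capture_output=True)
        if proc.returncode != 0:
            pytest.skip(f"Rscript/limma unavailable: {proc.stderr.decode()[:200]}")
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        res = moderated_t_test(df, list("def"), list("abc"))
        assert np.allclose(res["t_mod"], ref["t"], atol=1e-8)
        assert np.allclose(res["p"], ref["p"], atol=1e-8)


def _zero_prior():
    """The d0=0 (shrinkage-free) prior: ordinary pooled t."""
    return ShrinkageEstimate(d0=0.0, s0_sq=1.0)


class TestBHAdjust:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert np.allclose(q, [0.02, 0.04, 0.04, 0.02])

    def test_trivial_cases(self):
        assert bh_adjust([0.3]) == [0.3]
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_min_over_suffix_oracle(self, p):
        q = bh_adjust(p)
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        expected = [0.0] * m
        for rank, i in enumerate(order, start=1):
            expected[i] = min(1.0, min(
                p[j] * m / (r + 1)
                for r, j in enumerate(order) if r + 1 >= rank))
        assert np.allclose(q, expected, atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        srt = np.argsort(p, kind="stable")
        assert (np.diff(q[srt]) >= -1e-12).all()


class TestSelectDE:
    @pytest.mark.parametrize("q,log2fc,expected", [
        (0.001, math.log2(1.5), "up"),        # fold change exactly 1.5
        (0.001, math.log2(1.4), "ns"),        # below the up threshold
        (0.06, math.log2(3.0), "ns"),         # q fails
        (0.001, math.log2(0.67), "down"),     # boundary inclusive
        (0.001, math.log2(0.70), "ns"),
    ])
    def test_joint_thresholds(self, q, log2fc, expected):
        df = pd.DataFrame({"log2fc": [log2fc], "p": [q], "q": [q]})
        assert select_de(df)["status"].iloc[0] == expected

    def test_parameter_validation(self):
        df = pd.DataFrame({"log2fc": [0.0], "p": [0.5], "q": [0.5]})
        with pytest.raises(ValueError):
            select_de(df, fc_up=0.9)
        with pytest.raises(ValueError):
            select_de(df, fc_down=1.1)


class TestSplicingIndex:
    def test_concordant_gene_aggregated(self):
        si = splicing_index([2.0, 1.5])
        assert np.allclose(si, [0.25, -0.25])

    def test_discordant_gene_flagged(self):
        si = splicing_index([3.0, 0.5])
        assert np.allclose(si, [1.25, -1.25])

    def test_single_probe_set_gene(self):
        assert np.allclose(splicing_index([1.7]), [0.0])

    def test_aggregate_paths(self, rng):
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        base = rng.normal(8, 0.05, size=(4, 6))
        expr = pd.DataFrame(base, index=["g1_ps1", "g1_ps2", "g2_ps1", "g2_ps2"],
                            columns=cols)
        expr.loc["g1_ps1", ["b1", "b2", "b3"]] += 2.0     # concordant-ish pair
        expr.loc["g1_ps2", ["b1", "b2", "b3"]] += 1.5
        expr.loc["g2_ps1", ["b1", "b2", "b3"]] += 3.0     # discordant pair
        expr.loc["g2_ps2", ["b1", "b2", "b3"]] += 0.5
        de = moderated_t_test(expr, ["b1", "b2", "b3"], ["a1", "a2", "a3"])
        de["q"] = bh_adjust(de["p"].to_numpy())
        de = select_de(de)
        gs, gd = splicing_index_aggregate(
            de, expr, {"g1_ps1": "g1", "g1_ps2": "g1",
                       "g2_ps1": "g2", "g2_ps2": "g2"},
            ["b1", "b2", "b3"], ["a1", "a2", "a3"])
        assert not gs.loc["g1", "splice_flag"]
        assert gs.loc["g2", "splice_flag"]
        assert list(gd.index) == ["g1"]
        assert math.isclose(gd.loc["g1", "log2fc"], 1.75, abs_tol=0.1)


class TestSampleClustering:
    def test_identical_pair_merges_first_at_zero(self, rng):
        a = rng.normal(0, 1, 20)
        m = pd.DataFrame({"s1": a, "s2": a, "s3": rng.normal(0, 1, 20)})
        Z, order, newick, dropped = hierarchical_cluster_samples(m)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert set(Z[0, :2].astype(int)) == {0, 1}  # s1 and s2 merge first
        assert newick.count("(") == 2

    def test_matches_naive_upgma_oracle(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(20, 6)),
                         columns=[f"s{i}" for i in range(6)])
        Z, _, _, _ = hierarchical_cluster_samples(m)
        heights = naive_upgma_heights(m)
        assert np.allclose(np.sort(Z[:, 2]), np.sort(heights), atol=1e-10)

    def test_zero_variance_rows_dropped(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, size=(10, 4)))
        m.iloc[3] = 7.0
        _, _, _, dropped = hierarchical_cluster_samples(m)
        assert dropped == 1

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            hierarchical_cluster_samples(pd.DataFrame({"s1": [1.0, 2.0]}))


def naive_upgma_heights(matrix):
    """O(n^3) UPGMA over 1 - Pearson of z-scored rows; the reference oracle."""
    vals = matrix.to_numpy(dtype=float)
    vals = vals[vals.std(axis=1, ddof=1) > 0]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1,
                                                             keepdims=True)
    n = z.shape[1]
    d = {(i, j): 1 - np.corrcoef(z[:, i], z[:, j])[0, 1]
         for i in range(n) for j in range(i + 1, n)}
    clusters = {i: [i] for i in range(n)}
    heights = []
    nxt = n
    while len(clusters) > 1:
        (a, b), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        merged = clusters.pop(a) + clusters.pop(b)
        new_d = {}
        for (i, j), v in d.items():
            if a in (i, j) or b in (i, j):
                continue
            new_d[(i, j)] = v
        for c, members in clusters.items():
            pairs = [1 - np.corrcoef(z[:, x], z[:, y])[0, 1]
                     for x in merged for y in members]
            key = (min(c, nxt), max(c, nxt))
            new_d[key] = float(np.mean(pairs))
        clusters[nxt] = merged
        d = new_d
        nxt += 1
    return heights
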