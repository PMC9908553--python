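"""Downstream statistics: eBayes moderated t, Fisher/CMLE, post-hoc tests."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ensembletx.data import ContingencyTable2x2
from ensembletx.stats import (assign_age_bins, benjamini_hochberg,
                              estimate_variance_prior, fisher_exact_2x2,
                              games_howell, group_age_regression,
                              moderated_t_arrays, moderated_t_de,
                              mutation_classifier_metrics, oneway_anova,
                              welch_t)


class TestModeratedT:
    def _random_groups(self, seed=0, genes=30, n1=4, n2=5):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(genes, n1)), rng.normal(size=(genes, n2))

    def test_d0_zero_reproduces_ordinary_t(self):
        g1, g2 = self._random_groups()
        res = moderated_t_arrays(g1, g2, prior=(0.0, 1.0))
        t_ref, _ = sps.ttest_ind(g1, g2, axis=1)
        assert np.allclose(res["t"], t_ref, atol=1e-12)

    def test_d0_infinite_replaces_all_variances(self):
        g1, g2 = self._random_groups(seed=1)
        res = moderated_t_arrays(g1, g2, prior=(np.inf, 0.5))
        assert np.allclose(res["s2_post"], 0.5)

    def test_three_gene_worked_case_matches_scalar_formula(self):
        g1 = np.array([[1.0, 2.0, 3.0], [5.0, 5.5, 6.0], [0.0, 0.5, 1.0]])
        g2 = np.array([[0.0, 1.0, 2.0], [5.0, 5.0, 5.0], [2.0, 2.5, 3.0]])
        d0, s0_sq = 4.0, 0.25
        res = moderated_t_arrays(g1, g2, prior=(d0, s0_sq))
        for g in range(3):
            logfc = g1[g].mean() - g2[g].mean()
            rss = ((g1[g] - g1[g].mean()) ** 2).sum() + ((g2[g] - g2[g].mean()) ** 2).sum()
            s2 = rss / 4
            s2_post = (d0 * s0_sq + 4 * s2) / (d0 + 4)
            t_expected = logfc / np.sqrt(s2_post * (1 / 3 + 1 / 3))
            assert res["t"][g] == pytest.approx(t_expected, rel=1e-12)

    def test_prior_estimation_recovers_simulated_prior(self):
        """Variances drawn from scaled inv-chi2(d0=4, s0^2=0.09): the moment
        estimator lands near the truth with many genes."""
        rng = np.random.default_rng(7)
        d0_true, s0_sq_true, df = 4.0, 0.09, 10
        n_genes = 4000
        sigma2 = s0_sq_true * d0_true / rng.chisquare(d0_true, n_genes)
        s2 = sigma2 * rng.chisquare(df, n_genes) / df
        d0_hat, s0_sq_hat = estimate_variance_prior(s2, df)
        assert d0_hat == pytest.approx(d0_true, rel=0.25)
        assert s0_sq_hat == pytest.approx(s0_sq_true, rel=0.1)

    def test_zero_variance_gene_guarded(self):
        g1 = np.array([[1.0, 1.0, 1.0]])
        g2 = np.array([[0.0, 0.0, 0.0]])
        res = moderated_t_arrays(g1, g2, prior=(0.0, 1.0))
        assert np.isinf(res["t"][0])
        assert res["p_value"][0] == 0.0

    def test_de_table_flags_follow_thresholds(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        base = rng.normal(8, 1, 50)
        g1 = pd.DataFrame(base[:, None] + rng.normal(0, 0.2, (50, 6)), index=genes)
        g2 = pd.DataFrame(base[:, None] + rng.normal(0, 0.2, (50, 6)), index=genes)
        g1.iloc[:5] += 2.0  # strong shift in 5 genes
        table = moderated_t_de(g1, g2)
        assert (table["adj_p_value"] >= table["p_value"] - 1e-15).all()
        expected_flag = (table["adj_p_value"] < 0.01) & (table["logfc"].abs() > 0.1)
        assert (table["significant"] == expected_flag).all()
        assert table["significant"].iloc[:5].all()

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's lmFit + eBayes on the same matrix."""
        rng = np.random.default_rng(4)
        n1 = n2 = 5
        x = rng.normal(8, 1, (40, n1 + n2))
        x[:4, :n1] += 1.0
        frame = pd.DataFrame(x, index=[f"g{i}" for i in range(40)],
                             columns=[f"s{j}" for j in range(n1 + n2)])
        mat_path = tmp_path / "expr.tsv"
        out_path = tmp_path / "limma.tsv"
        frame.to_csv(mat_path, sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim("{mat_path}", row.names = 1))
            group <- factor(c(rep("a", {n1}), rep("b", {n2})), levels = c("b", "a"))
            design <- model.matrix(~group)
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t = fit$t[, 2], p = fit$p.value[, 2],
                              d0 = fit$df.prior, s0sq = fit$s2.prior)
            write.table(out, "{out_path}", sep = "\t", quote = FALSE)
        """)
        proc = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out_path, sep="\t")
        res = moderated_t_arrays(x[:, :n1], x[:, n1:])
        assert res["d0"] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert res["s0_sq"] == pytest.approx(ref["s0sq"].iloc[0], rel=1e-4)
        assert np.allclose(res["t"], ref["t"], rtol=1e-5, atol=1e-8)
        assert np.allclose(res["p_value"], ref["p"], rtol=1e-5, atol=1e-10)


class TestBenjaminiHochberg:
    def test_step_up_worked_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2]) == pytest.approx([0.2])

    def test_equal_ps_unchanged(self):
        assert benjamini_hochberg([0.3, 0.3, 0.3]) == pytest.approx([0.3] * 3)

    def test_direct_step_up_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        n = len(p)
        order = np.argsort(p)
        adj_sorted = p[order] * n / np.arange(1, n + 1)
        adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert benjamini_hochberg(p) == pytest.approx(expected)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


def _enumerate_fisher_p(a, b, c, d):
    """Exhaustive two-sided Fisher p over all tables with the same margins."""
    row1, col1, total = a + b, a + c, a + b + c + d
    lo = max(0, row1 + col1 - total)
    hi = min(row1, col1)
    pmf = {k: sps.hypergeom.pmf(k, total, col1, row1) for k in range(lo, hi + 1)}
    p_obs = pmf[a]
    return sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_below_mean_asd_vs_td_prenatal_events(self):
        res = fisher_exact_2x2(ContingencyTable2x2(20, 25, 24, 83))
        assert res.odds_ratio == pytest.approx(2.746, abs=5e-4)
        assert res.p_value == pytest.approx(0.0103, abs=5e-4)

    def test_below_vs_above_mean_prenatal_events(self):
        res = fisher_exact_2x2(ContingencyTable2x2(20, 25, 19, 60))
        assert res.odds_ratio == pytest.approx(2.506, abs=5e-4)
        assert res.p_value == pytest.approx(0.027, abs=5e-3)

    def test_uniform_table_is_null(self):
        res = fisher_exact_2x2(ContingencyTable2x2(1, 1, 1, 1))
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_signaled(self):
        res = fisher_exact_2x2(ContingencyTable2x2(0, 0, 3, 4))
        assert res.p_value == 1.0
        assert np.isnan(res.odds_ratio)

    def test_p_matches_exhaustive_enumeration_small_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            counts = rng.integers(0, 16, 4)
            if counts.sum() == 0 or counts.sum() > 60:
                continue
            a, b, c, d = (int(v) for v in counts)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            assert res.p_value == pytest.approx(
                _enumerate_fisher_p(a, b, c, d), abs=1e-10)

    def test_cmle_mean_matching_and_shrinkage(self):
        """The conditional MLE solves the mean equation to 1e-8 and shrinks
        the sample odds ratio toward 1."""
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 200:
            a, b, c, d = (int(v) for v in rng.integers(1, 25, 4))
            res = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
            psi = res.odds_ratio
            total, col1, row1 = a + b + c + d, a + c, a + b
            mean = sps.nchypergeom_fisher.mean(total, col1, row1, psi)
            assert abs(mean - a) < 1e-8
            sample_or = (a * d) / (b * c)
            lo, hi = sorted([1.0, sample_or])
            assert lo - 1e-9 <= psi <= hi + 1e-9
            checked += 1

    def test_cmle_matches_scipy_conditional_estimate(self):
        from scipy.stats.contingency import odds_ratio as scipy_or
        for table in [(20, 25, 24, 83), (7, 3, 2, 9), (1, 5, 6, 2)]:
            ours = fisher_exact_2x2(ContingencyTable2x2(*table)).odds_ratio
            ref = scipy_or(np.array(table).reshape(2, 2), kind="conditional").statistic
            assert ours == pytest.approx(ref, rel=1e-6)


class TestMutationClassifier:
    def test_printed_cohort_counts(self):
        accuracy, precision, recall, counts = mutation_classifier_metrics(13, 112, 12, 105)
        assert precision == pytest.approx(13 / 25)       # 52.0%
        assert round(accuracy * 100) == 49                # chance level
        assert recall == pytest.approx(13 / 112)          # exact ratio, 11.6%
        assert (counts.tp, counts.fn, counts.fp, counts.tn) == (13, 99, 12, 93)

    def test_no_carriers_edge(self):
        accuracy, precision, recall, _ = mutation_classifier_metrics(0, 10, 0, 20)
        assert recall == 0.0
        assert np.isnan(precision)
        assert accuracy == pytest.approx(20 / 30)


class TestWelchT:
    def test_identical_groups(self):
        t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_large_shift_drives_p_to_zero(self):
        rng = np.random.default_rng(0)
        _, _, p = welch_t(rng.normal(0, 1, 20), rng.normal(50, 1, 20))
        assert p < 1e-15

    def test_hand_worked_three_vs_three(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        t, df, p = welch_t(a, b)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 3 + vb / 3
        t_exp = (a.mean() - b.mean()) / np.sqrt(se2)
        df_exp = se2**2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        assert t == pytest.approx(t_exp)
        assert df == pytest.approx(df_exp)
        assert p == pytest.approx(2 * sps.t.sf(abs(t_exp), df_exp))


class TestOnewayAnova:
    def test_identical_groups_f_zero(self):
        f, _, _, p = oneway_anova([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
        assert f == pytest.approx(0.0)

    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 9)
        f, _, _, p_f = oneway_anova([a, b])
        t, p_t = sps.ttest_ind(a, b)  # pooled-variance t
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_three_group_hand_case(self):
        groups = [np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]),
                  np.array([6.0, 7.0, 8.0])]
        f, df1, df2, _ = oneway_anova(groups)
        grand = np.concatenate(groups).mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_exp = (ss_between / 2) / (ss_within / 6)
        assert (df1, df2) == (2, 6)
        assert f == pytest.approx(f_exp)


class TestGamesHowell:
    def test_identical_pair_has_p_one(self):
        res = games_howell({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0],
                            "c": [10.0, 11.0, 12.0]})
        row = res[(res["group_a"] == "a") & (res["group_b"] == "b")].iloc[0]
        assert row["adj_p_value"] == pytest.approx(1.0)

    def test_two_groups_reduces_to_welch(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 12)
        res = games_howell({"a": a, "b": b}).iloc[0]
        _, _, p_welch = welch_t(a, b)
        assert res["adj_p_value"] == pytest.approx(p_welch, abs=1e-10)

    def test_homoscedastic_balanced_matches_tukey_statistic(self):
        """With equal sample variances the Games-Howell q equals the Tukey
        q computed from the pooled variance."""
        base = np.array([-1.0, 0.0, 1.0])
        groups = {"a": base + 0.0, "b": base + 1.0, "c": base + 3.0}
        res = games_howell(groups)
        s2 = base.var(ddof=1)
        n = len(base)
        for _, row in res.iterrows():
            diff = abs(row["mean_diff"])
            q_tukey = diff / np.sqrt(s2 / n)
            assert row["q"] == pytest.approx(q_tukey, abs=1e-12)
            p_same_df = float(sps.studentized_range.sf(q_tukey, 3, row["df"]))
            assert row["adj_p_value"] == pytest.approx(p_same_df, abs=1e-6)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        data = pd.DataFrame({
            "score": np.concatenate([rng.normal(0, 1, 12), rng.normal(0.8, 2, 15),
                                     rng.normal(2, 0.5, 10)]),
            "group": ["a"] * 12 + ["b"] * 15 + ["c"] * 10,
        })
        ref = pingouin.pairwise_gameshowell(data=data, dv="score", between="group")
        ours = games_howell({g: data.loc[data["group"] == g, "score"].to_numpy()
                             for g in ("a", "b", "c")})
        merged = ours.merge(ref, left_on=["group_a", "group_b"], right_on=["A", "B"])
        assert len(merged) == 3
        assert np.allclose(merged["adj_p_value"], merged["pval"], atol=1e-6)


class TestAgeBins:
    def test_boundary_conventions(self):
        bins = assign_age_bins([19.9, 20.0, 30.9, 31.0, 49.0, 49.1])
        assert list(bins) == ["0-20", "20-31", "20-31", "31-49", "31-49", ">49"]

    def test_negative_age_errors(self):
        with pytest.raises(ValueError):
            assign_age_bins([-1.0])


class TestGroupAgeRegression:
    def test_constant_scores_give_zero_slopes(self):
        table = group_age_regression(
            np.ones(20), ["ASD"] * 10 + ["TD"] * 10, np.arange(20.0))
        assert np.allclose(table.loc[["group", "age", "group_x_age"], "coefficient"],
                           0.0, atol=1e-12)

    def test_pure_group_shift_recovered(self):
        rng = np.random.default_rng(4)
        n = 200
        dx = np.array(["ASD"] * (n // 2) + ["TD"] * (n // 2))
        ages = rng.uniform(12, 48, n)
        scores = 0.5 * (dx == "ASD") + rng.normal(0, 0.05, n)
        table = group_age_regression(scores, dx, ages)
        assert table.loc["group", "coefficient"] == pytest.approx(0.5, abs=0.05)
        assert table.loc["group", "p_value"] < 1e-6
        assert abs(table.loc["age", "coefficient"]) < 0.01
        assert abs(table.loc["group_x_age", "coefficient"]) < 0.01

    def test_collinear_design_names_column(self):
        dx = ["ASD"] * 5 + ["TD"] * 5
        ages = np.array([1.0] * 5 + [0.0] * 5)  # age == group indicator
        with pytest.raises(ValueError, match="collinear"):
            group_age_regression(np.arange(10.0), dx, ages)
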