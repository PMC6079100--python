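"""BioID chain: filtering, MNAR/MAR labels, imputation, normalization,
moderated t (with an independent moment-estimator oracle and an R/limma
cross-check), and BH adjustment."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from sortscreen import bioid, simulate
from sortscreen.bioid import (adjust_fdr, classify_missingness,
                              differential_abundance, filter_protein_groups,
                              impute, moderated_t_test, quantile_normalize)

GROUPS = pd.Series(
    ["control"] * 3 + ["bait"] * 3,
    index=["c1", "c2", "c3", "b1", "b2", "b3"],
)


def matrix(rows, index=None):
    return pd.DataFrame(
        rows,
        columns=GROUPS.index,
        index=index or [f"P{i}" for i in range(len(rows))],
    )


NA = np.nan


class TestFilter:
    @pytest.mark.parametrize(
        "row,expect_kept",
        [
            ([5, NA, NA, 6, NA, NA], False),   # (1 obs, 1 obs) -> filtered
            ([5, NA, NA, 6, 7, 8], True),      # deficient in one group only
            ([5, 6, 7, 8, 9, 10], True),       # fully observed
            ([NA, NA, NA, NA, NA, NA], False),
        ],
    )
    def test_two_value_rule(self, row, expect_kept):
        kept = filter_protein_groups(matrix([row]), GROUPS)
        assert bool(kept.iloc[0]) is expect_kept

    def test_small_groups_rejected(self):
        groups = pd.Series(["a", "b"], index=["s1", "s2"])
        with pytest.raises(ValueError):
            filter_protein_groups(
                pd.DataFrame([[1.0, 2.0]], columns=["s1", "s2"]), groups
            )


class TestClassify:
    def classify(self, rows):
        m = matrix(rows)
        kept = filter_protein_groups(m, GROUPS)
        return classify_missingness(m, GROUPS, kept)

    def test_requires_filter_mask(self):
        with pytest.raises(ValueError, match="filter"):
            classify_missingness(matrix([[1, 2, 3, 4, 5, 6]]), GROUPS)

    def test_group_absent_other_full_is_mnar(self):
        labels = self.classify([[NA, NA, NA, 6, 7, 8]])
        assert list(labels.iloc[0]) == ["MNAR", "MNAR", "MNAR", "", "", ""]

    def test_two_missing_other_full_is_mnar(self):
        labels = self.classify([[5, NA, NA, 6, 7, 8]])
        assert list(labels.iloc[0]) == ["", "MNAR", "MNAR", "", "", ""]

    def test_one_missing_per_group_is_mar(self):
        labels = self.classify([[5, 6, NA, 7, NA, 8]])
        assert (labels.iloc[0] == "MAR").sum() == 2

    def test_ambiguous_mixed_pattern_falls_back_to_mar(self):
        labels = self.classify([[5, NA, NA, 6, NA, 7]])
        assert (labels.iloc[0] == "MAR").sum() == 3
        assert (labels.iloc[0] == "MNAR").sum() == 0

    def test_simulated_unambiguous_patterns_recovered(self):
        """On simulated data, every cell classified MNAR under the strict
        rule was indeed generated by intensity-dependent dropout."""
        exp, truth = simulate.simulate_lfq_experiment(
            1500, 150, mnar_threshold_quantile=0.25, mar_rate=0.03, seed=42
        )
        kept = filter_protein_groups(exp.intensities, exp.groups)
        labels = classify_missingness(exp.intensities, exp.groups, kept)
        mech = truth.mechanism.loc[labels.index]
        g1 = exp.groups.index[exp.groups == "control"]
        g2 = exp.groups.index[exp.groups == "bait"]
        checked = 0
        for cols, other in ((list(g1), list(g2)), (list(g2), list(g1))):
            miss = exp.intensities.loc[labels.index, cols].isna()
            qualifying = (miss.sum(axis=1) >= 2) & exp.intensities.loc[
                labels.index, other].notna().all(axis=1)
            # rows where every missing cell truly came from dropout
            pure = qualifying & (mech[cols].where(miss, "MNAR") == "MNAR").all(
                axis=1)
            for c in cols:
                cells = pure & miss[c]
                checked += int(cells.sum())
                assert (labels.loc[cells, c] == "MNAR").all()
        assert checked > 50
        # symmetric one-missing-per-group patterns are labelled MAR exactly
        mar_cells = (labels == "MAR") & (mech == "MAR")
        assert mar_cells.sum().sum() > 0


class TestImpute:
    def test_mindet_uses_column_minimum(self):
        m = matrix([
            [5.1, 7.3, 8.0, 9.0, 9.1, 9.2],
            [NA, 7.4, 8.1, 9.3, 9.4, 9.5],
        ])
        labels = pd.DataFrame("", index=m.index, columns=m.columns)
        labels.iloc[1, 0] = "MNAR"
        out = impute(m, labels)
        assert out.iloc[1, 0] == 5.1

    def test_mindet_never_above_column_minimum(self):
        exp, _ = simulate.simulate_lfq_experiment(
            400, 40, mnar_threshold_quantile=0.3, seed=7
        )
        kept = filter_protein_groups(exp.intensities, exp.groups)
        labels = classify_missingness(exp.intensities, exp.groups, kept)
        data = exp.intensities.loc[kept]
        out = impute(data, labels)
        col_min = data.min(axis=0, skipna=True)
        for c in data.columns:
            imputed = data[c].isna() & (labels[c] == "MNAR")
            if imputed.any():
                assert (out.loc[imputed, c] <= col_min[c] + 1e-12).all()

    def test_complete_matrix_returned_unchanged(self):
        m = matrix([[1.0, 2, 3, 4, 5, 6]])
        labels = pd.DataFrame("", index=m.index, columns=m.columns)
        pd.testing.assert_frame_equal(impute(m, labels), m)

    def test_knn_k1_copies_nearest_neighbour(self):
        m = matrix([
            [1.0, 1.0, 1.0, 1.0, 1.0, NA],
            [1.0, 1.0, 1.0, 1.0, 1.0, 6.0],   # distance 0 -> nearest
            [9.0, 9.0, 9.0, 9.0, 9.0, 50.0],
        ])
        labels = pd.DataFrame("", index=m.index, columns=m.columns)
        labels.iloc[0, 5] = "MAR"
        out = impute(m, labels, k=1)
        assert out.iloc[0, 5] == 6.0

    def test_knn_mean_of_k_neighbours(self):
        m = matrix([
            [1.0, 1.0, 1.0, 1.0, 1.0, NA],
            [1.1, 1.0, 1.0, 1.0, 1.0, 6.0],
            [0.9, 1.0, 1.0, 1.0, 1.0, 8.0],
            [9.0, 9.0, 9.0, 9.0, 9.0, 50.0],
        ])
        labels = pd.DataFrame("", index=m.index, columns=m.columns)
        labels.iloc[0, 5] = "MAR"
        out = impute(m, labels, k=2)
        assert out.iloc[0, 5] == pytest.approx(7.0)

    def test_empty_column_rejected(self):
        m = matrix([[NA, 1, 1, 1, 1, 1], [NA, 2, 2, 2, 2, 2]])
        labels = pd.DataFrame("MAR", index=m.index, columns=m.columns)
        with pytest.raises(ValueError, match="no observed"):
            impute(m, labels)

    def test_no_missing_cells_remain(self):
        exp, _ = simulate.simulate_lfq_experiment(300, 30, seed=8)
        kept = filter_protein_groups(exp.intensities, exp.groups)
        labels = classify_missingness(exp.intensities, exp.groups, kept)
        out = impute(exp.intensities.loc[kept], labels)
        assert out.notna().all().all()


class TestQuantileNormalize:
    def test_two_column_rank_means(self):
        m = pd.DataFrame({"a": [1.0, 3.0], "b": [2.0, 8.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [1.5, 5.5]
        assert out["b"].tolist() == [1.5, 5.5]

    def test_order_preserved_within_column(self):
        m = pd.DataFrame({"a": [3.0, 1.0], "b": [2.0, 8.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [5.5, 1.5]

    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_sorted_columns_identical_property(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(50, 6)), columns=GROUPS.index)
        out = quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 6):
            assert np.max(np.abs(np.sort(out.iloc[:, j].to_numpy()) - ref)) \
                < 1e-12

    def test_missing_cells_rejected(self):
        m = matrix([[NA, 1, 1, 1, 1, 1]])
        with pytest.raises(ValueError):
            quantile_normalize(m)


def moderated_t_oracle(X1, X2):
    """Straight-line reimplementation of the moment equations: fit the
    scaled-F variance prior by matching mean/variance of log sample
    variances, solving the trigamma equation with brentq."""
    n1, n2 = X1.shape[1], X2.shape[1]
    d_g = n1 + n2 - 2
    delta = X2.mean(1) - X1.mean(1)
    s2 = (X1.var(1, ddof=1) * (n1 - 1) + X2.var(1, ddof=1) * (n2 - 1)) / d_g
    z = np.log(s2)
    e = z - special.digamma(d_g / 2) + np.log(d_g / 2)
    evar = e.var(ddof=1) - special.polygamma(1, d_g / 2)
    if evar > 0:
        target = evar / 2.0  # trigamma(d0/2) = evar  =>  solve for d0/2
        half_d0 = optimize.brentq(
            lambda y: special.polygamma(1, y) - evar, 1e-6, 1e8
        )
        d0 = 2 * half_d0
        s0 = np.exp(e.mean() + special.digamma(d0 / 2) - np.log(d0 / 2))
        s2_post = (d0 * s0 + d_g * s2) / (d0 + d_g)
        df = d0 + d_g
    else:
        s0 = np.exp(e.mean())
        s2_post = np.full_like(s2, s0)
        df = np.inf
    t = delta / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    if np.isinf(df):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


@pytest.fixture(scope="module")
def fixture_matrix():
    rng = np.random.default_rng(99)
    mu = np.zeros(200)
    mu[:20] = 1.5
    X1 = rng.normal(0, rng.uniform(0.5, 2.0, 200)[:, None], (200, 3))
    X2 = rng.normal(mu[:, None], 1.0, (200, 3))
    return pd.DataFrame(np.hstack([X1, X2]), columns=GROUPS.index)


class TestModeratedT:
    def test_d0_zero_equals_pooled_t(self, fixture_matrix):
        res = moderated_t_test(fixture_matrix, GROUPS, d0_override=0.0)
        X1 = fixture_matrix[GROUPS.index[:3]].to_numpy()
        X2 = fixture_matrix[GROUPS.index[3:]].to_numpy()
        t_ref, p_ref = stats.ttest_ind(X2.T, X1.T, equal_var=True)
        assert np.allclose(res.table["t"], t_ref, atol=1e-10)
        assert np.allclose(res.table["p_value"], p_ref, atol=1e-10)

    def test_d0_infinite_gives_constant_posterior_variance(self,
                                                           fixture_matrix):
        res = moderated_t_test(fixture_matrix, GROUPS, d0_override=np.inf)
        assert np.allclose(res.table["s2_post"], res.s0_sq)

    def test_matches_independent_oracle(self, fixture_matrix):
        res = moderated_t_test(fixture_matrix, GROUPS)
        X1 = fixture_matrix[GROUPS.index[:3]].to_numpy()
        X2 = fixture_matrix[GROUPS.index[3:]].to_numpy()
        t_ref, p_ref = moderated_t_oracle(X1, X2)
        assert np.allclose(res.table["t"], t_ref, atol=1e-6)
        assert np.allclose(res.table["p_value"], p_ref, atol=1e-6)

    def test_posterior_variance_between_prior_and_sample(self,
                                                         fixture_matrix):
        res = moderated_t_test(fixture_matrix, GROUPS)
        lo = np.minimum(res.table["s2"], res.s0_sq)
        hi = np.maximum(res.table["s2"], res.s0_sq)
        assert ((res.table["s2_post"] >= lo - 1e-12)
                & (res.table["s2_post"] <= hi + 1e-12)).all()

    def test_all_zero_variance_falls_back_with_warning(self):
        m = matrix([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]] * 3)
        with pytest.warns(UserWarning, match="ordinary t"):
            moderated_t_test(m, GROUPS)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_r_limma(self, fixture_matrix, tmp_path):
        """Cross-check t statistics against limma's eBayes on the same
        matrix (independent reference implementation)."""
        data_path = tmp_path / "m.tsv"
        out_path = tmp_path / "out.tsv"
        fixture_matrix.to_csv(data_path, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(f"""
suppressMessages(library(limma))
m <- as.matrix(read.delim("{data_path}", row.names=1))
design <- cbind(Intercept=1, bait=c(0,0,0,1,1,1))
fit <- eBayes(lmFit(m, design))
write.table(data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior),
            "{out_path}", sep="\t", quote=FALSE)
""")
        proc = subprocess.run(["Rscript", str(script)], capture_output=True,
                              text=True)
        assert proc.returncode == 0, proc.stderr
        ref = pd.read_csv(out_path, sep="\t")
        res = moderated_t_test(fixture_matrix, GROUPS)
        assert np.allclose(res.table["t"].to_numpy(), ref["t"].to_numpy(),
                           atol=1e-6)
        assert res.d0 == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-4)


class TestFdr:
    def test_bh_hand_example(self):
        assert np.allclose(adjust_fdr([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_fdr([0.2])[0] == pytest.approx(0.2)

    def test_monotone_in_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        adj = adjust_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])


class TestPipeline:
    def test_full_chain_runs_and_covers_missingness(self):
        exp, truth = simulate.simulate_lfq_experiment(500, 50, seed=17)
        table, res = differential_abundance(exp)
        assert table["p_value"].between(0, 1).all()
        assert {"log_fc", "fdr", "n_mnar", "n_mar"} <= set(table.columns)
        # label bookkeeping covers every missing cell of kept proteins
        kept_missing = exp.intensities.loc[table.index].isna().sum().sum()
        assert (table["n_mnar"] + table["n_mar"]).sum() == kept_missing
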