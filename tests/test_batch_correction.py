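"""Batch-effect removal methods and the EB model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import crossarray as ca

from conftest import make_merged


def frame(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


def batch_series(labels, columns):
    return pd.Series(list(labels), index=columns)


# ---------------------------------------------------------------------------
# independent step-by-step EB reference (plain loops, no shared code paths)
# ---------------------------------------------------------------------------


def reference_eb(Y, labels, tol=1e-4, max_iter=200):
    Y = np.asarray(Y, dtype=float)
    G, N = Y.shape
    batches = list(dict.fromkeys(labels))
    cols = {b: [j for j, l in enumerate(labels) if l == b] for b in batches}
    # per-gene batch means, weighted grand mean, pooled variance
    alpha, sigma2 = [], []
    batch_mean = []
    for g in range(G):
        means = {b: sum(Y[g, j] for j in cols[b]) / len(cols[b]) for b in batches}
        a = sum(len(cols[b]) * means[b] for b in batches) / N
        rss = sum((Y[g, j] - means[labels[j]]) ** 2 for j in range(N))
        alpha.append(a)
        sigma2.append(rss / N)
        batch_mean.append(means)
    # standardize
    Z = np.zeros_like(Y)
    for g in range(G):
        for j in range(N):
            Z[g, j] = (Y[g, j] - alpha[g]) / np.sqrt(sigma2[g])
    out = np.zeros_like(Y)
    for b in batches:
        n = len(cols[b])
        g_hat = [sum(Z[g, j] for j in cols[b]) / n for g in range(G)]
        d2_hat = [
            sum((Z[g, j] - g_hat[g]) ** 2 for j in cols[b]) / n for g in range(G)
        ]
        g_bar = float(np.mean(g_hat))
        t2 = float(np.var(g_hat, ddof=1))
        m = float(np.mean(d2_hat))
        s2 = float(np.var(d2_hat, ddof=1))
        g_star = list(g_hat)
        d2_star = list(d2_hat)
        if s2 > 0 or t2 > 0:
            lam = (2 * s2 + m * m) / s2 if s2 > 0 else None
            th = (m * s2 + m ** 3) / s2 if s2 > 0 else None
            for _ in range(max_iter):
                change = 0.0
                g_new, d2_new = [], []
                for g in range(G):
                    if t2 > 0:
                        gn = (n * t2 * g_hat[g] + d2_star[g] * g_bar) / (
                            n * t2 + d2_star[g]
                        )
                    else:
                        gn = g_bar
                    if lam is not None:
                        sum2 = n * (d2_hat[g] + (g_hat[g] - gn) ** 2)
                        dn = (th + 0.5 * sum2) / (n / 2 + lam - 1)
                    else:
                        dn = d2_hat[g]
                    change = max(change, abs(gn - g_star[g]), abs(dn - d2_star[g]))
                    g_new.append(gn)
                    d2_new.append(dn)
                g_star, d2_star = g_new, d2_new
                if change < tol:
                    break
        for g in range(G):
            for j in cols[b]:
                out[g, j] = (
                    np.sqrt(sigma2[g]) * (Z[g, j] - g_star[g]) / np.sqrt(d2_star[g])
                    + alpha[g]
                )
    return out


class TestCombatEB:
    def test_identical_batches_return_input(self):
        rng = np.random.default_rng(0)
        block = rng.normal(8, 1, (50, 6))
        values = frame(np.hstack([block, block]))
        batch = batch_series("A" * 6 + "B" * 6, values.columns)
        adjusted, params = ca.combat_eb(values, batch)
        assert np.allclose(adjusted, values, atol=1e-8)
        assert np.allclose(params.gamma_hat, 0.0, atol=1e-12)
        assert np.allclose(params.delta2_hat, 1.0, atol=1e-12)

    def test_toy_matrix_matches_stepwise_reference(self):
        rng = np.random.default_rng(42)
        Y = rng.normal(7, 2, (3, 4))
        Y[:, 2:] += 1.5  # batch shift
        values = frame(Y)
        labels = ["a", "a", "b", "b"]
        adjusted, _ = ca.combat_eb(values, batch_series(labels, values.columns))
        expected = reference_eb(Y, labels)
        assert np.allclose(adjusted.to_numpy(), expected, atol=1e-8)

    def test_larger_matrix_matches_stepwise_reference(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(8, 1, (30, 9))
        labels = ["a"] * 3 + ["b"] * 2 + ["c"] * 4
        Y[:, 3:5] -= 2.0
        Y[:, 5:] *= 1.3
        values = frame(Y)
        adjusted, _ = ca.combat_eb(values, batch_series(labels, values.columns))
        assert np.allclose(adjusted.to_numpy(), reference_eb(Y, labels), atol=1e-8)

    def test_parameter_recovery(self, eb_recovery):
        p = eb_recovery["params"]
        gamma, delta2 = eb_recovery["gamma"], eb_recovery["delta2"]
        sigma = np.sqrt(p.sigma2.to_numpy())
        # estimand of gamma_star: the size-weighted centered batch effect
        centered = gamma.sub(gamma.mean(axis=1), axis=0).to_numpy()
        est = p.gamma_star.to_numpy() * sigma[:, None]
        corr = np.corrcoef(est.ravel(), centered.ravel())[0, 1]
        assert corr >= 0.9
        # estimand of delta2_star: batch variance relative to pooled variance
        d2 = delta2.to_numpy()
        rel = np.abs(p.delta2_star.to_numpy() - d2 / d2.mean(axis=1, keepdims=True))
        rel /= d2 / d2.mean(axis=1, keepdims=True)
        assert np.median(rel) <= 0.20

    def test_identity_limit_without_batch_effects(self):
        # gamma = 0 and delta2 = 1: the adjustment should vanish with n
        rng = np.random.default_rng(3)
        Y = rng.uniform(4, 12, (500, 1)) + rng.standard_normal((500, 100))
        values = frame(Y)
        batch = batch_series(["A"] * 50 + ["B"] * 50, values.columns)
        adjusted, _ = ca.combat_eb(values, batch)
        assert np.mean(np.abs(adjusted.to_numpy() - Y)) < 0.05

    def test_supervised_mode_protects_group_signal(self):
        rng = np.random.default_rng(11)
        n = 8
        # group confounded-ish with batch composition: unbalanced groups
        labels = ["A"] * n + ["B"] * n
        groups = ["x"] * 6 + ["y"] * 2 + ["x"] * 2 + ["y"] * 6
        Y = rng.normal(8, 0.3, (200, 2 * n))
        Y[:50, np.array(groups) == "y"] += 2.0  # biology
        Y[:, np.array(labels) == "B"] += 1.0  # batch
        values = frame(Y)
        batch = batch_series(labels, values.columns)
        covs = pd.DataFrame({"group": groups}, index=values.columns)
        sup, _ = ca.combat_eb(values, batch, covs)
        unsup, _ = ca.combat_eb(values, batch)
        def group_sep(M):
            gy = M[:50][:, np.array(groups) == "y"].mean()
            gx = M[:50][:, np.array(groups) == "x"].mean()
            return gy - gx
        assert group_sep(sup.to_numpy()) == pytest.approx(2.0, abs=0.3)
        # unbalanced design: unsupervised correction erodes the group signal
        assert group_sep(sup.to_numpy()) > group_sep(unsup.to_numpy())

    def test_confounded_design_rejected(self):
        values = frame(np.random.default_rng(0).normal(size=(10, 6)))
        batch = batch_series("AAABBB", values.columns)
        covs = pd.DataFrame({"g": ["x", "x", "x", "y", "y", "y"]}, index=values.columns)
        with pytest.raises(ca.ValidationError, match="confounded"):
            ca.combat_eb(values, batch, covs)

    def test_small_batch_rejected(self):
        values = frame(np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.raises(ca.ValidationError, match=">= 2 samples"):
            ca.combat_eb(values, batch_series("AAAAB", values.columns))

    def test_single_batch_rejected(self):
        values = frame(np.random.default_rng(0).normal(size=(10, 4)))
        with pytest.raises(ca.ValidationError, match="two batches"):
            ca.combat_eb(values, batch_series("AAAA", values.columns))


class TestMeanCenter:
    def test_hand_worked_example(self):
        values = frame([[1.0, 3.0, 5.0, 7.0]])
        out = ca.mean_center(values, batch_series("AABB", values.columns))
        assert np.allclose(out, [[3.0, 5.0, 3.0, 5.0]])

    def test_equal_means_and_constant_gene_unchanged(self):
        values = frame([[2.0, 4.0, 2.0, 4.0], [5.0, 5.0, 5.0, 5.0]])
        out = ca.mean_center(values, batch_series("AABB", values.columns))
        assert np.allclose(out, values)

    def test_batch_means_equal_grand_mean(self):
        rng = np.random.default_rng(2)
        values = frame(rng.normal(size=(40, 12)))
        labels = list("AAAABBBBCCCC")
        out = ca.mean_center(values, batch_series(labels, values.columns)).to_numpy()
        grand = out.mean(axis=1)
        for b in "ABC":
            cols = np.array(labels) == b
            assert np.max(np.abs(out[:, cols].mean(axis=1) - grand)) < 1e-10


class TestQuantileNormalize:
    def test_sort_average_oracle(self):
        values = frame(np.array([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0]]))
        out = ca.quantile_normalize(values)
        assert np.allclose(out.to_numpy(), [[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])

    def test_identical_columns_unchanged(self):
        col = np.array([[1.0], [5.0], [2.0]])
        values = frame(np.hstack([col, col, col]))
        assert np.allclose(ca.quantile_normalize(values), values)

    def test_ties_get_mean_of_tied_rank_values(self):
        values = frame(np.array([[2.0, 1.0], [2.0, 3.0], [4.0, 5.0]]))
        out = ca.quantile_normalize(values)
        # reference = (1.5, 2.5, 4.5); tied cells share mean(1.5, 2.5) = 2
        assert np.allclose(out.to_numpy()[:, 0], [2.0, 2.0, 4.5])
        assert np.allclose(out.to_numpy()[:, 1], [1.5, 2.5, 4.5])

    def test_columns_share_sorted_multiset(self):
        rng = np.random.default_rng(4)
        values = frame(rng.normal(size=(100, 7)))
        out = ca.quantile_normalize(values).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 7):
            assert np.allclose(np.sort(out[:, j]), ref, atol=1e-12)


class TestGeneQuantileNormalize:
    def test_single_batch_keeps_order_statistics(self):
        rng = np.random.default_rng(5)
        values = frame(rng.normal(size=(20, 6)))
        out = ca.gene_quantile_normalize(
            values, batch_series("AAAAAA", values.columns)
        )
        for g in range(20):
            assert np.allclose(np.sort(out.to_numpy()[g]), np.sort(values.to_numpy()[g]))

    def test_shifted_batch_medians_align(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, (50, 8))
        Y = np.hstack([base[:, :4], base[:, 4:] + 10.0])
        values = frame(Y)
        out = ca.gene_quantile_normalize(
            values, batch_series("AAAABBBB", values.columns)
        ).to_numpy()
        med_a = np.median(out[:, :4], axis=1)
        med_b = np.median(out[:, 4:], axis=1)
        assert np.allclose(med_a, med_b, atol=1e-12)

    def test_within_batch_order_preserved(self):
        rng = np.random.default_rng(7)
        values = frame(rng.normal(size=(30, 9)))
        labels = "AAABBBCCC"
        out = ca.gene_quantile_normalize(
            values, batch_series(labels, values.columns)
        ).to_numpy()
        Y = values.to_numpy()
        for b in "ABC":
            cols = np.array(list(labels)) == b
            for g in range(30):
                order = np.argsort(Y[g, cols])
                assert np.all(np.diff(out[g, cols][order]) >= 0)


class TestMedianRankScores:
    def test_hand_worked_reference_profile(self):
        Y = np.array([[1.0, 3.0, 10.0], [2.0, 4.0, 30.0], [3.0, 5.0, 20.0]])
        values = frame(Y)
        out = ca.median_rank_scores(
            values, batch_series(["r", "r", "t"], values.columns), "r"
        )
        assert np.allclose(out.to_numpy()[:, 2], [2.0, 4.0, 3.0])
        assert np.allclose(out.to_numpy()[:, :2], Y[:, :2])  # reference unchanged

    def test_single_reference_sample_permutes_its_values(self):
        Y = np.array([[5.0, 9.0], [1.0, 4.0], [3.0, 7.0]])
        values = frame(Y)
        out = ca.median_rank_scores(
            values, batch_series(["r", "t"], values.columns), "r"
        ).to_numpy()
        assert sorted(out[:, 1]) == sorted(Y[:, 0])
        assert np.argsort(out[:, 1]).tolist() == np.argsort(Y[:, 1]).tolist()

    def test_already_aligned_target_unchanged(self):
        Y = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        values = frame(Y)
        out = ca.median_rank_scores(
            values, batch_series(["r", "t"], values.columns), "r"
        )
        assert np.allclose(out, Y)

    def test_default_reference_largest_batch_lexicographic_tie(self):
        rng = np.random.default_rng(8)
        values = frame(rng.normal(size=(10, 4)))
        out = ca.median_rank_scores(values, batch_series("zzaa", values.columns))
        # tie between 'z' and 'a' -> 'a' wins; its columns stay untouched
        assert np.allclose(out.to_numpy()[:, 2:], values.to_numpy()[:, 2:])

    def test_sorted_targets_equal_reference_profile(self):
        rng = np.random.default_rng(9)
        values = frame(rng.normal(size=(25, 6)))
        labels = ["r", "r", "r", "t", "t", "u"]
        out = ca.median_rank_scores(
            values, batch_series(labels, values.columns), "r"
        ).to_numpy()
        profile = np.median(np.sort(values.to_numpy()[:, :3], axis=0), axis=1)
        for j in (3, 4, 5):
            assert np.array_equal(np.sort(out[:, j]), profile)

    def test_absent_reference_rejected(self):
        values = frame(np.zeros((3, 2)))
        with pytest.raises(ca.ValidationError, match="not present"):
            ca.median_rank_scores(values, batch_series("ab", values.columns), "zzz")


class TestQuantileDiscretize:
    def test_quantile_rule_oracle(self):
        values = frame(np.array([[1.0], [2.0], [3.0], [4.0]]))
        out = ca.quantile_discretize(values, q=2)
        assert out.to_numpy()[:, 0].tolist() == [1.0, 1.0, 2.0, 2.0]

    def test_constant_sample_degenerates_to_bin_one(self):
        values = frame(np.full((5, 1), 3.0))
        assert np.all(ca.quantile_discretize(values, q=4).to_numpy() == 1.0)

    def test_monotone_step_function_with_codomain(self):
        rng = np.random.default_rng(10)
        values = frame(rng.normal(size=(60, 3)))
        out = ca.quantile_discretize(values, q=8).to_numpy()
        assert set(np.unique(out)) <= set(range(1, 9))
        Y = values.to_numpy()
        for j in range(3):
            order = np.argsort(Y[:, j])
            assert np.all(np.diff(out[order, j]) >= 0)

    def test_too_many_bins_rejected(self):
        values = frame(np.zeros((3, 1)))
        with pytest.raises(ca.ValidationError, match="exceeds"):
            ca.quantile_discretize(values, q=5)


class TestNorDi:
    def test_value_at_mean_is_zero(self):
        rng = np.random.default_rng(11)
        col = rng.normal(0, 1, 99)
        col[0] = col[1:].mean()
        out = ca.nordi(frame(col[:, None])).to_numpy()
        assert out[0, 0] == 0.0

    def test_tail_fraction_matches_alpha(self):
        rng = np.random.default_rng(12)
        n = 10000
        values = frame(rng.standard_normal((n, 1)))
        out = ca.nordi(values, alpha_outlier=0.05, alpha_disc=0.05).to_numpy()
        frac = np.mean(out != 0)
        se = np.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.10) <= 3 * se

    def test_extreme_outlier_removed_then_labelled_positive(self):
        rng = np.random.default_rng(13)
        col = rng.standard_normal(500)
        col[7] = 1e6
        out = ca.nordi(frame(col[:, None])).to_numpy()
        assert out[7, 0] == 1.0
        # thresholds computed from the cleaned sample: tails still populated
        assert 0.02 < np.mean(out != 0) < 0.25

    def test_codomain(self):
        rng = np.random.default_rng(14)
        out = ca.nordi(frame(rng.normal(size=(50, 4)))).to_numpy()
        assert set(np.unique(out)) <= {-1.0, 0.0, 1.0}

    def test_too_few_values_rejected(self):
        with pytest.raises(ca.ValidationError, match="at least 3"):
            ca.nordi(frame(np.zeros((2, 1))))

    def test_bad_alpha_rejected(self):
        with pytest.raises(ca.ValidationError, match="alpha_disc"):
            ca.nordi(frame(np.zeros((5, 1))), alpha_disc=0.7)


class TestDispatcher:
    def test_none_returns_identical_values(self):
        rng = np.random.default_rng(15)
        merged = make_merged(rng.normal(size=(20, 6)), batches="AAABBB")
        out = ca.remove_batch_effects(merged, "NONE")
        assert out.values.equals(merged.values)
        out2 = ca.remove_batch_effects(merged, "none")
        assert out2.values.equals(merged.values)

    def test_unknown_method_lists_valid_values(self):
        merged = make_merged(np.zeros((3, 4)), batches="AABB")
        with pytest.raises(ca.ValidationError, match="EB, MC, QN, GQ, MRS, QD, NorDi"):
            ca.remove_batch_effects(merged, "XPN")

    def test_methods_preserve_shape_and_ids(self):
        rng = np.random.default_rng(16)
        merged = make_merged(rng.normal(8, 1, (30, 9)), batches="AAABBBCCC")
        for method in ("EB", "MC", "QN", "GQ", "MRS", "QD", "NorDi"):
            out = ca.remove_batch_effects(merged, method)
            assert out.feature_ids == merged.feature_ids
            assert out.sample_ids == merged.sample_ids
            assert not out.values.isna().to_numpy().any()

    def test_discretized_output_refuses_continuous_readjustment(self):
        rng = np.random.default_rng(17)
        merged = make_merged(rng.normal(size=(20, 6)), batches="AAABBB")
        discretized = ca.remove_batch_effects(merged, "QD")
        assert discretized.discretized
        with pytest.raises(ca.ValidationError, match="discretized"):
            ca.remove_batch_effects(discretized, "EB")

    def test_covariates_only_for_eb(self):
        merged = make_merged(np.zeros((3, 4)), batches="AABB")
        with pytest.raises(ca.ValidationError, match="supervised"):
            ca.remove_batch_effects(merged, "MC", covariate_columns=["g"])

    def test_missing_covariate_column_rejected(self):
        rng = np.random.default_rng(18)
        samples = [f"s{j}" for j in range(6)]
        info = ca.SampleInfoTable(pd.DataFrame(
            [(s, s, "A" if j < 3 else "B") for j, s in enumerate(samples)],
            columns=["Array.name", "Sample.name", "Batch"],
        ))
        merged = make_merged(rng.normal(size=(10, 6)), batches="AAABBB",
                             samples=samples, sample_info=info)
        with pytest.raises(ca.ValidationError, match="celltype"):
            ca.remove_batch_effects(merged, "EB", covariate_columns=["celltype"])
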