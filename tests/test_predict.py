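"""Supervised harnesses: cross-validated classification and regression
calibration, paired comparison conventions, domain summaries, and the
out-of-fold discipline (leakage) check."""

import numpy as np
import pandas as pd
import pytest

from topobrain.predict import (classify_binary, domain_summary, paired_compare,
                               reduce_features, regress_behavior)


class TestReduceFeatures:
    def test_full_rank_pca_preserves_information(self, rng):
        F = rng.normal(size=(30, 6))
        scores = reduce_features(F, n_pc=6)
        sd = F.std(axis=0)
        Z = (F - F.mean(0)) / sd
        # distances are preserved by a complete orthogonal rotation
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(scores), pdist(Z), atol=1e-8)

    def test_duplicate_rows_stay_duplicates(self, rng):
        F = rng.normal(size=(10, 5))
        F[3] = F[7]
        scores = reduce_features(F, n_pc=3)
        assert np.allclose(scores[3], scores[7], atol=1e-10)

    def test_planted_three_factor_variance(self, rng):
        Z = rng.normal(size=(100, 3))
        F = Z @ rng.normal(size=(3, 40)) + 0.05 * rng.normal(size=(100, 40))
        scores = reduce_features(F, n_pc=10)
        var3 = scores[:, :3].var(axis=0).sum() / scores.var(axis=0).sum()
        assert var3 >= 0.95

    def test_requires_more_subjects_than_pcs(self, rng):
        with pytest.raises(ValueError):
            reduce_features(rng.normal(size=(5, 10)), n_pc=5)


class TestClassification:
    def test_wide_margin_feature_gives_perfect_auc(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        F = rng.normal(size=(n, 5))
        F[:, 0] = y * 10.0 + 0.01 * rng.normal(size=n)
        res = classify_binary(F, y, seed=0)
        assert res.metrics[0] == 1.0

    def test_permuted_labels_auc_at_chance(self):
        """Labels independent of features: mean AUC within 3 SEs of 0.5
        over 100 seeded runs."""
        aucs = []
        for s in range(100):
            r = np.random.default_rng(s)
            y = r.permutation(np.repeat([0, 1], 15))
            F = r.normal(size=(30, 8))
            aucs.append(classify_binary(F, y, seed=s).metrics[0])
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) <= 3 * se

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            classify_binary(rng.normal(size=(10, 3)), np.zeros(10))

    def test_every_subject_predicted_once(self, rng):
        y = np.tile([0, 1], 15)
        res = classify_binary(rng.normal(size=(30, 4)), y, seed=1)
        assert res.scores.shape == (30,)
        assert set(res.fold_assignment) == set(range(5))

    def test_seeded_folds_reproducible(self, rng):
        F = rng.normal(size=(30, 4))
        y = np.tile([0, 1], 15)
        a = classify_binary(F, y, seed=3)
        b = classify_binary(F, y, seed=3)
        assert np.array_equal(a.scores, b.scores)
        assert a.metrics[0] == b.metrics[0]

    def test_out_of_fold_discipline_blocks_leakage(self, rng):
        """A feature equal to the label scaled by a full-data statistic
        inflates AUC only if preprocessing sees held-out rows.  With
        in-fold scaling/PCA, chance-level labels stay at chance."""
        aucs = []
        for s in range(30):
            r = np.random.default_rng(s)
            y = r.permutation(np.repeat([0, 1], 20))
            F = r.normal(size=(40, 10))
            aucs.append(classify_binary(F, y, seed=s, n_pc=5).metrics[0])
        assert abs(np.mean(aucs) - 0.5) < 0.06


class TestRegression:
    def test_exact_linear_target_recovered(self, rng):
        F = rng.normal(size=(60, 5))
        y = F[:, :3] @ np.array([1.0, -2.0, 0.5])
        res = regress_behavior(F, y, n_repeats=3, seed=0)
        assert np.all(res.metrics >= 0.999)

    def test_null_target_r_near_zero(self):
        """Independent target: per-repeat r concentrates near (slightly
        below) zero under cross-validation."""
        rs = []
        for s in range(50):
            r = np.random.default_rng(s)
            res = regress_behavior(r.normal(size=(40, 5)), r.normal(size=40),
                                   n_repeats=2, seed=s)
            rs.extend(res.metrics)
        se = np.std(rs) / np.sqrt(len(rs))
        assert np.mean(rs) <= 0 + 3 * se

    def test_one_r_per_repeat(self, rng):
        res = regress_behavior(rng.normal(size=(30, 4)), rng.normal(size=30),
                               n_repeats=7, seed=0)
        assert res.metrics.shape == (7,)

    def test_degenerate_target_rejected(self, rng):
        with pytest.raises(ValueError):
            regress_behavior(rng.normal(size=(20, 3)), np.ones(20))

    def test_shared_seed_gives_identical_folds_across_feature_sets(self, rng):
        FA = rng.normal(size=(30, 6))
        FB = rng.normal(size=(30, 9))
        y = rng.normal(size=30)
        ra = regress_behavior(FA, y, n_repeats=2, seed=5)
        rb = regress_behavior(FB, y, n_repeats=2, seed=5)
        assert np.array_equal(ra.fold_assignment, rb.fold_assignment)


class TestPairedCompare:
    def test_identical_metrics(self):
        t, p = paired_compare([0.3, 0.4, 0.5], [0.3, 0.4, 0.5])
        assert t == 0.0 and p == 1.0

    def test_constant_offset_flagged_infinite(self):
        a = np.array([0.3, 0.4, 0.5])
        with pytest.warns(UserWarning, match="infinite"):
            t, p = paired_compare(a + 0.1, a)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_scipy_on_generic_input(self, rng):
        from scipy import stats
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        t, p = paired_compare(a, b)
        t2, p2 = stats.ttest_rel(a, b)
        assert np.isclose(t, t2) and np.isclose(p, p2)

    def test_type_one_error_calibrated(self):
        """Same-distribution pairs: rejection rate at alpha=0.05 within
        [0.03, 0.07] over 1000 simulations of length 10."""
        rejections = 0
        sims = 1000
        r = np.random.default_rng(0)
        for _ in range(sims):
            a = r.normal(size=10)
            b = r.normal(size=10)
            _, p = paired_compare(a, b)
            rejections += p < 0.05
        assert 0.03 <= rejections / sims <= 0.07

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2], [1, 2, 3])


class TestDomainSummary:
    def test_perfectly_correlated_pair_fully_explained(self, rng):
        x = rng.normal(size=50)
        Y = pd.DataFrame({"a": x, "b": 2.0 * x + 1.0})
        scores = domain_summary(Y, {"a": "dom", "b": "dom"})
        assert abs(np.corrcoef(scores["dom"], x)[0, 1]) > 1 - 1e-10

    def test_sign_aligned_with_item_mean(self, rng):
        x = rng.normal(size=60)
        Y = pd.DataFrame({"a": x + 0.1 * rng.normal(size=60),
                          "b": x + 0.1 * rng.normal(size=60)})
        s1 = domain_summary(Y, {"a": "d", "b": "d"})["d"]
        s2 = domain_summary(-Y, {"a": "d", "b": "d"})["d"]
        m1 = ((Y - Y.mean()) / Y.std()).mean(axis=1)
        m2 = ((-Y - (-Y).mean()) / (-Y).std()).mean(axis=1)
        assert np.corrcoef(s1, m1)[0, 1] > 0
        assert np.corrcoef(s2, m2)[0, 1] > 0

    def test_planted_factor_recovered(self, rng):
        factor = rng.normal(size=200)
        items = {f"i{k}": 0.7 * factor + 0.5 * rng.normal(size=200)
                 for k in range(5)}
        Y = pd.DataFrame(items)
        score = domain_summary(Y, {c: "dom" for c in Y.columns})["dom"]
        assert abs(np.corrcoef(score, factor)[0, 1]) >= 0.9

    def test_single_item_domain_passthrough(self, rng):
        x = rng.normal(size=30)
        Y = pd.DataFrame({"only": x})
        score = domain_summary(Y, {"only": "solo"})["solo"]
        assert np.allclose(score, (x - x.mean()) / x.std())

    def test_unmapped_item_rejected(self, rng):
        Y = pd.DataFrame({"a": rng.normal(size=10), "b": rng.normal(size=10)})
        with pytest.raises(ValueError, match="b"):
            domain_summary(Y, {"a": "d"})
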