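"""CCA pipeline: behavioral filtering rules, confound regression algebra,
first-mode recovery and permutation calibration, and the interpretation
operations (ROI contributions, behavior loadings)."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import CCA as SkCCA

from topobrain.cca import (cca_first_mode, deconfound, filter_behaviors,
                           roi_contributions, top_behavior_loadings)
from topobrain.landscapes import FeatureLayout


class TestFilterBehaviors:
    def test_clean_matrix_fully_kept(self, rng):
        Y = pd.DataFrame(rng.normal(size=(30, 6)),
                         columns=[f"i{k}" for k in range(6)])
        kept_df, kept = filter_behaviors(Y)
        assert kept == list(Y.columns)

    def test_constructed_violations_dropped(self, rng):
        """10 items, 3 planted violations (missingness, zero variance,
        dominant category) -> exactly 7 kept."""
        n = 40
        data = {f"ok{k}": rng.normal(size=n) for k in range(7)}
        missing = rng.normal(size=n)
        missing[:10] = np.nan  # 25% missing > 10% threshold
        data["too_missing"] = missing
        data["constant"] = np.full(n, 3.14)
        dominant = np.zeros(n)
        dominant[0] = 1.0  # 97.5% one value > 95% threshold
        data["dominant"] = dominant
        Y = pd.DataFrame(data)
        _, kept = filter_behaviors(Y)
        assert sorted(kept) == sorted(f"ok{k}" for k in range(7))

    def test_all_dropped_is_error(self):
        Y = pd.DataFrame({"a": np.ones(20)})
        with pytest.raises(ValueError):
            filter_behaviors(Y)

    def test_duplicate_names_rejected(self, rng):
        Y = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "x"])
        with pytest.raises(ValueError):
            filter_behaviors(Y)


class TestDeconfound:
    def test_intercept_only_centers_columns(self, rng):
        X = rng.normal(size=(20, 4)) + 5.0
        out = deconfound(X)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(out, X - X.mean(axis=0), atol=1e-12)

    def test_exact_linear_dependence_gives_zero_residuals(self, rng):
        C = rng.normal(size=(30, 2))
        X = C @ rng.normal(size=(2, 5)) + 7.0
        out = deconfound(X, C)
        assert np.max(np.abs(out)) <= 1e-10

    def test_residuals_orthogonal_to_confounds(self, rng):
        X = rng.normal(size=(40, 6))
        C = rng.normal(size=(40, 3))
        out = deconfound(X, C)
        assert np.max(np.abs(out.T @ C)) <= 1e-8

    def test_collinear_confounds_named(self, rng):
        c = rng.normal(size=40)
        C = np.column_stack([c, 2.0 * c])
        with pytest.raises(ValueError, match="collinear"):
            deconfound(rng.normal(size=(40, 2)), C)


class TestFirstMode:
    def test_identical_matrices_give_r1_of_one(self, rng):
        X = rng.normal(size=(50, 8))
        res = cca_first_mode(X, X.copy(), n_pc=5, n_perm=99, seed=0)
        assert np.isclose(res.r1, 1.0, atol=1e-10)

    def test_r1_invariant_to_invertible_transform(self, rng):
        X = rng.normal(size=(60, 6))
        Y = X @ rng.normal(size=(6, 5)) + 0.5 * rng.normal(size=(60, 5))
        A = rng.normal(size=(5, 5)) + 2 * np.eye(5)
        r_a = cca_first_mode(X, Y, n_pc=5, n_perm=9, seed=0).r1
        r_b = cca_first_mode(X, Y @ A, n_pc=5, n_perm=9, seed=0).r1
        assert np.isclose(r_a, r_b, atol=1e-8)

    def test_agrees_with_sklearn_cca(self, rng):
        """Dual route: the SVD-based first canonical correlation matches
        scikit-learn's NIPALS CCA on the same PC scores."""
        X = rng.normal(size=(80, 10))
        Y = 0.5 * X[:, :6] + rng.normal(size=(80, 6))
        res = cca_first_mode(X, Y, n_pc=5, n_perm=9, seed=0)
        from topobrain.cca import _pca_scores, _zscore
        Xp, _ = _pca_scores(_zscore(X), 5)
        Yp, _ = _pca_scores(_zscore(Y), 5)
        sk = SkCCA(n_components=1, max_iter=2000).fit(Xp, Yp)
        u, v = sk.transform(Xp, Yp)
        r_sk = abs(np.corrcoef(u[:, 0], v[:, 0])[0, 1])
        assert np.isclose(res.r1, r_sk, atol=1e-6)

    def test_variates_correlate_at_r1(self, rng):
        X = rng.normal(size=(40, 8))
        Y = X[:, :4] + rng.normal(size=(40, 4))
        res = cca_first_mode(X, Y, n_pc=4, n_perm=9, seed=1)
        r = abs(np.corrcoef(res.x_variate, res.y_variate)[0, 1])
        assert np.isclose(r, res.r1, atol=1e-10)

    def test_permutation_p_floor(self, rng):
        X = rng.normal(size=(50, 5))
        res = cca_first_mode(X, X.copy(), n_pc=3, n_perm=199, seed=0)
        assert np.isclose(res.p_perm, 1.0 / 200)

    def test_null_p_roughly_uniform(self):
        """No association: p > 0.05 in the vast majority of replicates."""
        hits = 0
        reps = 40
        for s in range(reps):
            r = np.random.default_rng(s)
            res = cca_first_mode(r.normal(size=(60, 10)),
                                 r.normal(size=(60, 8)),
                                 n_pc=5, n_perm=99, seed=s)
            hits += res.p_perm > 0.05
        assert hits >= int(0.85 * reps)

    def test_too_many_pcs_rejected(self, rng):
        with pytest.raises(ValueError, match="n_pc"):
            cca_first_mode(rng.normal(size=(20, 5)), rng.normal(size=(20, 5)),
                           n_pc=25, n_perm=9)

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 6))
        a = cca_first_mode(X, Y, n_pc=4, n_perm=49, seed=7)
        b = cca_first_mode(X, Y, n_pc=4, n_perm=49, seed=7)
        assert np.array_equal(a.perm_null, b.perm_null)
        assert a.p_perm == b.p_perm


class TestInterpretation:
    def _setup(self, rng, n=40):
        layout = FeatureLayout(rois=(0, 1, 2), dims=(0, 1), k=2, n_bins=5)
        F = rng.normal(size=(n, layout.n_features))
        return layout, F

    def test_roi_matching_variate_scores_one(self, rng):
        layout, F = self._setup(rng)
        variate = F[:, layout.columns_for(0, 0)].mean(axis=1)
        variate = (variate - variate.mean()) / variate.std()
        # make ROI 0 / H0 block rank-one in the variate direction
        F[:, layout.columns_for(0, 0)] = np.outer(variate,
                                                  np.linspace(1, 2, 10))
        res = _fake_result(variate)
        contrib = roi_contributions(F, layout, res, ["A", "A", "B"])
        row = contrib.roi_table.query("roi == 0 and dim == 0")
        assert np.isclose(abs(row["contribution"].iloc[0]), 1.0, atol=1e-8)

    def test_noise_roi_contribution_near_zero(self, rng):
        layout, F = self._setup(rng, n=200)
        variate = rng.normal(size=200)
        contrib = roi_contributions(F, layout, _fake_result(variate),
                                    ["A", "A", "B"])
        assert contrib.roi_table["contribution"].abs().max() <= 2 / np.sqrt(200) * 2.5

    def test_network_tables_cover_all_networks(self, rng):
        layout, F = self._setup(rng)
        contrib = roi_contributions(F, layout, _fake_result(rng.normal(size=40)),
                                    ["A", "B", "B"])
        assert set(contrib.network_table["network"]) == {"A", "B"}
        assert set(contrib.network_tests["network"]) == {"A", "B"}

    def test_top_loadings_ranked_and_signed(self, rng):
        n = 100
        v = rng.normal(size=n)
        Y = pd.DataFrame({
            "pos": v + 0.1 * rng.normal(size=n),
            "neg": -v + 0.1 * rng.normal(size=n),
            "null": rng.normal(size=n),
        })
        table = top_behavior_loadings(Y, _fake_result(v), k=2)
        assert list(table["item"]) in (["pos", "neg"], ["neg", "pos"])
        assert table.loc[table["item"] == "pos", "loading"].iloc[0] > 0.9
        assert table.loc[table["item"] == "neg", "loading"].iloc[0] < -0.9

    def test_loadings_invariant_to_item_rescaling(self, rng):
        v = rng.normal(size=50)
        Y = pd.DataFrame({"a": v + rng.normal(size=50),
                          "b": rng.normal(size=50)})
        t1 = top_behavior_loadings(Y, _fake_result(v), k=2)
        t2 = top_behavior_loadings(Y * 100.0, _fake_result(v), k=2)
        assert np.allclose(t1["loading"], t2["loading"])

    def test_k_zero_empty(self, rng):
        Y = pd.DataFrame({"a": rng.normal(size=20)})
        assert len(top_behavior_loadings(Y, _fake_result(rng.normal(size=20)),
                                         k=0)) == 0

    def test_k_beyond_items_warns(self, rng):
        Y = pd.DataFrame({"a": rng.normal(size=20)})
        with pytest.warns(UserWarning, match="item count"):
            table = top_behavior_loadings(Y, _fake_result(rng.normal(size=20)),
                                          k=5)
        assert len(table) == 1


def _fake_result(variate):
    from topobrain.cca import CcaModeResult
    return CcaModeResult(r1=0.5, p_perm=0.01, perm_null=np.zeros(1),
                         x_variate=np.asarray(variate),
                         y_variate=np.asarray(variate),
                         feature_weights=np.zeros(1),
                         behavior_weights=np.zeros(1))
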