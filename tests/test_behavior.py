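import numpy as np
import pandas as pd
import pytest

from msvolt.behavior import (FeatureMatrix, build_features, roc_auc,
                             nested_cv_classify, region_connectivity,
                             sme_contrast, group_test_fdr,
                             DEFAULT_PENALTY_GRID)
from msvolt.spectral import PowerTensor


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def make_labels(n, sessions, p_recall=0.5, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"recalled": rng.random(n) < p_recall,
                         "session": np.asarray(sessions)})


class TestBuildFeatures:
    def test_volatility_mode_one_feature_per_electrode(self, rng):
        vol = rng.normal(size=(40, 5, 30))
        labels = make_labels(40, np.repeat([0, 1], 20))
        fm = build_features(vol, labels, mode="volatility")
        assert fm.X.shape == (40, 5)
        for s in (0, 1):
            sel = labels["session"].to_numpy() == s
            np.testing.assert_allclose(fm.X[sel].mean(axis=0), 0, atol=1e-9)
            np.testing.assert_allclose(fm.X[sel].std(axis=0), 1, atol=1e-9)

    def test_power_mode_flattens_electrode_frequency(self, rng):
        pt = PowerTensor(power=rng.normal(size=(20, 3, 4)),
                         freqs=np.array([10., 20., 30., 40.]))
        labels = make_labels(20, np.zeros(20, dtype=int))
        fm = build_features(pt, labels, mode="power")
        assert fm.X.shape == (20, 12)

    def test_nan_feature_named(self, rng):
        X = rng.normal(size=(10, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="event 3, feature 1"):
            FeatureMatrix(X=X, y=np.tile([0, 1], 5),
                          session_ids=np.zeros(10, dtype=int))


class TestRocAuc:
    def test_hand_example(self):
        assert roc_auc(np.array([0.1, 0.4, 0.35, 0.8]),
                       np.array([0, 0, 1, 1])) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc(np.array([1, 2, 8, 9.]), np.array([0, 0, 1, 1])) == 1.0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels))

    def test_chance_level_for_random_labels(self, rng):
        scores = rng.normal(size=10 ** 4)
        labels = rng.integers(0, 2, 10 ** 4)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestNestedCV:
    def _features(self, n_sessions, n_per, n_feat, effect, seed):
        rng = np.random.default_rng(seed)
        n = n_sessions * n_per
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, n_feat))
        k = max(1, n_feat // 5)
        X[:, :k] += effect * y[:, None]  # shift 20% of features
        return FeatureMatrix(X=X, y=y,
                             session_ids=np.repeat(np.arange(n_sessions),
                                                   n_per))

    def test_null_features_near_chance(self):
        fm = self._features(4, 100, 20, effect=0.0, seed=11)
        res = nested_cv_classify(fm)
        assert 0.45 <= res["auc"].mean() <= 0.55

    def test_planted_effect_detected(self):
        fm = self._features(4, 100, 20, effect=1.0, seed=12)
        res = nested_cv_classify(fm)
        assert res["auc"].mean() > 0.85

    def test_event_duplication_invariance(self):
        fm = self._features(3, 40, 5, effect=0.5, seed=13)
        dup = FeatureMatrix(X=np.repeat(fm.X, 2, axis=0),
                            y=np.repeat(fm.y, 2),
                            session_ids=np.repeat(fm.session_ids, 2))
        a = nested_cv_classify(fm)
        b = nested_cv_classify(dup)
        # ranking is preserved; tiny deviations arise because the L2 penalty
        # acts on the total (not per-sample) loss, so duplication slightly
        # rescales the effective regularization
        np.testing.assert_allclose(a["auc"], b["auc"], atol=0.02)

    def test_single_class_session_skipped(self, rng):
        X = rng.normal(size=(90, 4))
        y = np.r_[np.ones(30, int), rng.integers(0, 2, 60)]
        fm = FeatureMatrix(X=X, y=y, session_ids=np.repeat([0, 1, 2], 30))
        with pytest.warns(RuntimeWarning, match="one class"):
            res = nested_cv_classify(fm)
        assert set(res["session"]) <= {1, 2}

    def test_requires_three_sessions(self, rng):
        fm = FeatureMatrix(X=rng.normal(size=(40, 3)),
                           y=np.tile([0, 1], 20),
                           session_ids=np.repeat([0, 1], 20))
        with pytest.raises(ValueError, match="3 sessions"):
            nested_cv_classify(fm)


class TestRegionConnectivity:
    def test_single_electrode_per_region(self):
        beta = np.array([[0.5, 0.1], [-0.2, 0.6]])
        C = region_connectivity(beta, ["Hipp", "PRC"])
        # influence of Hipp on PRC = beta[PRC row, Hipp col]
        assert C.loc["Hipp", "PRC"] == -0.2
        assert C.loc["PRC", "Hipp"] == 0.1

    def test_block_means_hand_computed(self):
        beta = np.arange(1.0, 17.0).reshape(4, 4)
        labels = ["A", "A", "B", "B"]
        C = region_connectivity(beta, labels)
        # C[A→B]: target rows 2,3 × source cols 0,1 → (9+10+13+14)/4
        assert C.loc["A", "B"] == pytest.approx(11.5)
        assert C.loc["B", "A"] == pytest.approx((3 + 4 + 7 + 8) / 4)
        assert C.loc["A", "A"] == pytest.approx((1 + 2 + 5 + 6) / 4)

    def test_single_region_collapses_to_grand_mean(self, rng):
        beta = rng.normal(size=(3, 3))
        C = region_connectivity(beta, ["Hipp"] * 3)
        assert C.loc["Hipp", "Hipp"] == pytest.approx(beta.mean())

    def test_matches_double_loop_oracle(self, rng):
        labels = list(rng.choice(["Hipp", "EC", "PRC"], size=6))
        beta = rng.normal(size=(6, 6))
        C = region_connectivity(beta, labels)
        for I in set(labels):
            for Jr in set(labels):
                vals = [beta[j, i] for j in range(6) for i in range(6)
                        if labels[j] == Jr and labels[i] == I]
                assert C.loc[I, Jr] == pytest.approx(np.mean(vals))


class TestSMEContrast:
    def test_identical_networks_zero(self, rng):
        C = pd.DataFrame(rng.normal(size=(3, 3)), index=list("abc"),
                         columns=list("abc"))
        np.testing.assert_allclose(sme_contrast(C, C).to_numpy(), 0.0)

    def test_no_antisymmetry_imposed(self):
        regions = ["Hipp", "PRC"]
        CR = pd.DataFrame([[0.0, -0.3], [0.2, 0.0]], index=regions,
                          columns=regions)
        CN = pd.DataFrame(0.0, index=regions, columns=regions)
        d = sme_contrast(CR, CN)
        assert d.loc["Hipp", "PRC"] != -d.loc["PRC", "Hipp"]

    def test_mismatched_regions_rejected(self):
        a = pd.DataFrame(np.zeros((2, 2)), index=["x", "y"], columns=["x", "y"])
        b = pd.DataFrame(np.zeros((2, 2)), index=["x", "z"], columns=["x", "z"])
        with pytest.raises(ValueError, match="region"):
            sme_contrast(a, b)


def subject_deltas(values, regions=("EC", "Hipp", "PHC", "PRC")):
    return [pd.DataFrame(v, index=list(regions), columns=list(regions))
            for v in values]


class TestGroupTestFDR:
    def test_all_zero_deltas(self):
        deltas = subject_deltas(np.zeros((12, 4, 4)))
        res = group_test_fdr(deltas, min_subjects=10)
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_allclose(res.t.to_numpy()[off], 0.0)
        np.testing.assert_allclose(res.p.to_numpy()[off], 1.0)

    def test_adjusted_p_dominates_raw(self, rng):
        deltas = subject_deltas(rng.normal(0, 0.05, (15, 4, 4)))
        res = group_test_fdr(deltas, min_subjects=10)
        off = ~np.eye(4, dtype=bool)
        assert np.all(res.p_adj.to_numpy()[off] >= res.p.to_numpy()[off])

    def test_small_cells_excluded_before_adjustment(self, rng):
        vals = rng.normal(0, 0.05, (15, 4, 4))
        vals[5:, 0, 1] = np.nan  # only 5 subjects contribute to EC→Hipp
        res = group_test_fdr(subject_deltas(vals), min_subjects=10)
        assert np.isnan(res.p_adj.iloc[0, 1])
        assert res.n_subjects.iloc[0, 1] == 5

    def test_null_false_discovery_rate_controlled(self, rng):
        """BH holds the FDR near the nominal level under the global null."""
        n_rep, fdr_hits = 1000, 0
        for _ in range(n_rep):
            deltas = rng.normal(0.0, 0.04, (48, 4, 4))
            res = group_test_fdr(subject_deltas(deltas), min_subjects=10)
            off = ~np.eye(4, dtype=bool)
            fdr_hits += np.nansum(res.p_adj.to_numpy()[off] < 0.05) > 0
        rate = fdr_hits / n_rep
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            group_test_fdr([])
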