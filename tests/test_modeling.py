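"""Ridge logistic fitting, cross-validation, AUC and subset enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.special import expit

from remodelnet.metrics import confusion_at_threshold, roc_auc
from remodelnet.modeling import (RidgeLogit, cross_validated_probabilities,
                                 stratified_folds, subset_search)
from conftest import small_config
from remodelnet.synthetic import simulate_expression


class TestRidgeLogit:
    def test_symmetric_balanced_data_zero_intercept(self, rng):
        x = rng.normal(0, 1, size=(20, 2))
        X = np.vstack([x, -x])
        y = np.array([1.0] * 20 + [0.0] * 20)
        res = RidgeLogit(y, X, ridge=1.0).fit()
        assert abs(res.params["const"]) < 1e-6

    def test_infinite_ridge_limit_recovers_base_rate(self, rng):
        x = rng.normal(0, 1, size=(30, 1))
        y = (rng.random(30) < 0.7).astype(float)
        res = RidgeLogit(y, x, ridge=1e12).fit()
        assert np.abs(res.params.iloc[1:]).max() < 1e-4
        base = y.mean()
        assert res.params["const"] == pytest.approx(np.log(base / (1 - base)), abs=1e-3)

    def test_separable_toy_matches_oracle_optimizer(self):
        """Penalized objective value agrees with scipy.optimize on the same loss."""
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])[:, None]
        y = np.array([0.0, 0, 0, 1, 1, 1])
        ridge = 1e-4  # strong enough that the optimum is numerically well-defined
        res = RidgeLogit(y, x, ridge=ridge).fit(max_iter=500)

        def objective(beta):
            eta = beta[0] + x[:, 0] * beta[1]
            nll = np.sum(np.logaddexp(0, eta) - y * eta)
            return nll + 0.5 * ridge * beta[1] ** 2

        oracle = minimize(objective, np.zeros(2), method="BFGS",
                          options={"gtol": 1e-10}).fun
        ours = objective(res.params.to_numpy())
        assert ours == pytest.approx(oracle, abs=1e-4)
        preds = res.predict(x) >= 0.5
        assert (preds == y.astype(bool)).all()
        assert np.isfinite(res.params).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            RidgeLogit(np.ones(5), np.arange(5.0))


class TestCrossValidation:
    def _toy(self, n=24, effect=2.0, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([True] * (n // 2) + [False] * (n // 2))
        X = rng.normal(0, 1, size=(n, 3))
        X[y] += effect  # per-feature shift in units of the noise SD
        features = pd.DataFrame(X, index=[f"s{i}" for i in range(n)],
                                columns=["a", "b", "c"])
        return features, y

    def test_leave_one_out_scores_every_sample_once(self):
        features, y = self._toy(n=12)
        ev = cross_validated_probabilities(features, y, k=12, seed=0)
        assert ev.oof_probabilities.notna().all()
        assert sorted(ev.fold_assignment.unique()) == list(range(12))

    def test_fixed_seed_reproducible(self):
        features, y = self._toy()
        e1 = cross_validated_probabilities(features, y, k=10, seed=42)
        e2 = cross_validated_probabilities(features, y, k=10, seed=42)
        pd.testing.assert_series_equal(e1.oof_probabilities, e2.oof_probabilities)
        assert e1.auc == e2.auc

    def test_strong_planted_signal_has_high_auc_in_most_seeds(self):
        hits = sum(
            cross_validated_probabilities(*self._toy(n=32, effect=2.0, seed=s),
                                          k=10, seed=s).auc >= 0.85
            for s in range(20)
        )
        assert hits >= 18

    def test_label_permutation_auc_centred_at_half(self):
        features, _ = self._toy(n=32, effect=0.0, seed=1)
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(50):
            y_perm = rng.permutation([True] * 16 + [False] * 16)
            aucs.append(cross_validated_probabilities(features, y_perm, k=10,
                                                      seed=3).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_stratification_preserves_class_proportions(self):
        y = np.array([True] * 20 + [False] * 12)
        folds = stratified_folds(y, 4, seed=0)
        for f in range(4):
            sel = folds == f
            assert y[sel].sum() == 5
            assert (~y[sel]).sum() == 3

    def test_k_validated(self):
        features, y = self._toy()
        with pytest.raises(ValueError):
            cross_validated_probabilities(features, y, k=1)


class TestRocAuc:
    def test_trivial_cases(self):
        assert roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5
        # pair-counting example: cases {0.9, 0.4}, controls {0.7, 0.6}
        assert roc_auc([0.9, 0.4, 0.7, 0.6], [1, 1, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.lists(st.floats(-5, 5), min_size=4, max_size=20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_transform_invariance_and_label_flip(self, scores):
        n = len(scores)
        labels = np.arange(n) % 2 == 0
        # coarse grid so the monotone transform cannot collapse distinct scores
        scores = np.round(np.asarray(scores), 2)
        auc = roc_auc(scores, labels)
        assert roc_auc(expit(scores * 3.0) + 1.0, labels) == pytest.approx(auc)
        assert roc_auc(scores, ~labels) == pytest.approx(1.0 - auc)


class TestConfusion:
    def test_perfect_and_degenerate_classifiers(self):
        y = [1, 1, 0, 0]
        tpr, fpr, _ = confusion_at_threshold([1, 1, 0, 0], y)
        assert (tpr, fpr) == (100.0, 0.0)
        tpr, fpr, _ = confusion_at_threshold([1, 1, 1, 1], y)
        assert (tpr, fpr) == (100.0, 100.0)

    def test_hand_counted_rates_at_16_16(self):
        y = np.array([True] * 16 + [False] * 16)
        p = np.concatenate([np.r_[np.ones(13), np.zeros(3)],
                            np.r_[np.ones(2), np.zeros(14)]])
        tpr, fpr, table = confusion_at_threshold(p, y)
        assert tpr == pytest.approx(81.25)
        assert fpr == pytest.approx(12.5)
        assert table.counts.loc["low", "low"] == 13
        assert table.counts.loc["high", "low"] == 2


class TestSubsetSearch:
    def test_single_candidate_single_evaluation(self):
        cfg = small_config(n_genes=50, n_de=5, n_annotated=10, n_overlap=0,
                           overlap_direction=None, n_nodes=20, module_sizes=(),
                           plant_trio=False)
        expr, samples, _ = simulate_expression(cfg)
        evs, missing = subset_search([expr.index[0]], expr, samples, max_size=1, k=5)
        assert len(evs) == 1 and missing == []
        assert evs[0].feature_ids == (expr.index[0],)

    def test_combinatorial_count_for_14_candidates(self):
        cfg = small_config(n_genes=100, n_de=5, n_annotated=10, n_overlap=0,
                           overlap_direction=None, n_nodes=20, module_sizes=(),
                           plant_trio=False)
        expr, samples, _ = simulate_expression(cfg)
        cand = list(expr.index[:14])
        evs, _ = subset_search(cand, expr, samples, max_size=3, k=5,
                               include_full=False)
        assert len(evs) == 14 + 91 + 364  # C(14,1)+C(14,2)+C(14,3) = 469
        evs_full, _ = subset_search(cand, expr, samples, max_size=3, k=5,
                                    include_full=True)
        assert len(evs_full) == 470

    def test_missing_candidates_excluded_and_reported(self):
        cfg = small_config(n_genes=50, n_de=5, n_annotated=10, n_overlap=0,
                           overlap_direction=None, n_nodes=20, module_sizes=(),
                           plant_trio=False)
        expr, samples, _ = simulate_expression(cfg)
        evs, missing = subset_search([expr.index[0], "NOT_A_GENE"], expr, samples,
                                     max_size=2, k=5)
        assert missing == ["NOT_A_GENE"]
        assert all("NOT_A_GENE" not in ev.feature_ids for ev in evs)

    def test_ranking_is_exhaustive_best_first(self):
        cfg = small_config(n_genes=60, seed=5, n_de=10, n_annotated=20, n_overlap=0,
                           overlap_direction=None, n_nodes=30, module_sizes=(),
                           plant_trio=False)
        expr, samples, _ = simulate_expression(cfg)
        evs, _ = subset_search(list(expr.index[:6]), expr, samples, max_size=2, k=5)
        assert all(evs[0].auc >= ev.auc for ev in evs)
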