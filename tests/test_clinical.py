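"""Validation statistics: rank tests, marker/clinical models, reclassification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from remodelnet.clinical import (ClassificationTable,
                                 classification_table_metrics, clinical_model,
                                 fisher_exact_2x2, mann_whitney_test,
                                 marker_association, nri_individual,
                                 nri_net_from_tables, spearman_association)
from conftest import small_config
from remodelnet.synthetic import simulate_clinical


class TestSpearman:
    def test_monotone_and_reversed(self):
        x = np.arange(10.0)
        rho, _ = spearman_association(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_association(x, -x**3)
        assert rho == pytest.approx(-1.0)

    def test_exact_p_matches_enumeration_oracle_n5(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 5])
        rho, p = spearman_association(x, y)
        # oracle: all 5! permutations of y
        rhos = []
        for perm in itertools.permutations(y):
            r = np.corrcoef(x, perm)[0, 1]  # ranks equal values here
            rhos.append(r)
        p_oracle = np.mean([abs(r) >= abs(rho) - 1e-12 for r in rhos])
        assert p == pytest.approx(p_oracle)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman_association([1, 1, 1, 1], [1, 2, 3, 4])


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        u, p = mann_whitney_test([1.0, 2, 3], [1.0, 2, 3])
        assert u == pytest.approx(4.5)
        assert p == 1.0

    def test_complete_separation_3v3_exact(self):
        u, p = mann_whitney_test([1.0, 2, 3], [10.0, 11, 12])
        assert p == pytest.approx(2 / 20)

    def test_u_complement_identity(self, rng):
        a = rng.normal(size=9)
        b = rng.normal(size=7)
        ua, _ = mann_whitney_test(a, b)
        ub, _ = mann_whitney_test(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])


class TestFisher:
    def test_diagonal_table_exact_probability(self):
        p, _ = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)

    def test_balanced_table_p_one(self):
        p, odds = fisher_exact_2x2([[2, 2], [2, 2]])
        assert p == 1.0 and odds == 1.0

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [3, 4]])


class TestMarkerAssociation:
    def _samples(self, n=115, seed=0):
        return simulate_clinical(small_config(seed=seed), n=n)

    def test_constant_marker_null(self):
        s = self._samples()
        res = marker_association(np.ones(len(s)), s, form="linear")
        assert res.slope == pytest.approx(0.0)
        assert res.auc == 0.5

    def test_ef_itself_perfectly_separates(self):
        s = self._samples()
        res = marker_association(s["ef_percent"], s, form="logistic")
        assert res.auc == pytest.approx(1.0)

    def test_copula_biomarker_auc_matches_derived_expectation(self):
        """At Spearman -0.28 with a 61/54 class split, the copula implies
        AUC = Phi(r * (E[z|low] - E[z|high]) / (sd * sqrt(2))) ~ 0.63.

        (latent r = 2 sin(pi * 0.28 / 6) = 0.293; truncated-normal group means
        at the 53rd-percentile split give a 0.47-SD latent separation.)
        """
        aucs = [marker_association(t["biomarker"], t, form="linear").auc
                for t in (self._samples(seed=s) for s in range(20))]
        assert abs(np.mean(aucs) - 0.633) < 0.04  # ~3 SE of the 20-seed mean
        assert all(0.5 <= a <= 0.8 for a in aucs)
        # association direction: higher marker, lower EF
        res = marker_association(self._samples(seed=3)["biomarker"],
                                 self._samples(seed=3), form="linear")
        assert res.slope < 0


class TestClinicalModel:
    def _samples(self, targets, n=115, seed=0):
        cfg = small_config(clinical_targets=targets, seed=seed)
        return simulate_clinical(cfg, n=n)

    def test_null_covariate_p_uniform_mean(self):
        ps = []
        for seed in range(50):
            t = self._samples({"age": -0.35, "sex": 0.0,
                               "time_to_reperfusion": 0.0}, seed=seed)
            res = clinical_model(t)
            ps.append(res.pvalues["time_to_reperfusion"])
        assert abs(np.mean(ps) - 0.5) < 0.12

    def test_duplicate_marker_leaves_auc_unchanged(self):
        t = self._samples({"age": -0.35, "sex": 0.2, "time_to_reperfusion": -0.26})
        t = t.assign(age_copy=t["age"])
        base = clinical_model(t)
        with pytest.warns(UserWarning, match="collinear"):
            dup = clinical_model(t, add_marker="age_copy")
        assert dup.auc == pytest.approx(base.auc, abs=1e-6)

    def test_constant_covariate_rejected(self):
        t = self._samples({"age": -0.35, "sex": 0.2, "time_to_reperfusion": -0.26})
        t = t.assign(flat=1.0)
        with pytest.raises(ValueError):
            clinical_model(t, covariates=("age", "flat"))

    def test_summary_mentions_auc(self):
        t = self._samples({"age": -0.35, "sex": 0.2, "time_to_reperfusion": -0.26})
        assert "AUC" in clinical_model(t).summary()


class TestClassificationTable:
    @pytest.mark.parametrize("correct,total,expected", [
        (32, 54, 59.3), (43, 54, 79.6), (38, 61, 62.3),
    ])
    def test_percent_correct_rounding(self, correct, total, expected):
        table = classification_table_metrics([[correct, total - correct], [5, 5]])
        assert table.per_class_correct_rounded["high"] == expected

    def test_perfect_table(self):
        table = classification_table_metrics([[10, 0], [0, 20]])
        assert table.per_class_correct_rounded.tolist() == [100.0, 100.0]
        assert table.total_correct_rounded == 100.0

    def test_empty_true_class_rejected(self):
        with pytest.raises(ValueError):
            classification_table_metrics([[0, 0], [3, 4]])


class TestNri:
    def test_no_movement_zero(self):
        p = np.array([0.2, 0.8, 0.3, 0.9])
        res = nri_individual(p, p, [1, 1, 0, 0])
        assert res.nri == 0.0

    def test_direct_formula_example(self):
        """10 cases (3 up, 1 down), 10 controls (1 up, 2 down) -> 30 %."""
        y = np.array([True] * 10 + [False] * 10)
        old = np.full(20, 0.4)
        old[[3, 15, 16]] = 0.6  # 1 case and 2 controls start above threshold
        new = old.copy()
        new[[0, 1, 2]] = 0.7    # 3 cases move up
        new[3] = 0.3            # 1 case moves down
        new[[10]] = 0.8         # 1 control moves up
        new[[15, 16]] = 0.2     # 2 controls move down
        res = nri_individual(old, new, y)
        assert res.nri == pytest.approx(30.0)
        assert (res.case_up, res.case_down) == (0.3, 0.1)
        assert (res.control_up, res.control_down) == (0.1, 0.2)

    def test_label_swap_negates_nri(self, rng):
        old = rng.random(30)
        new = rng.random(30)
        y = rng.random(30) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        a = nri_individual(old, new, y).nri
        b = nri_individual(old, new, ~y).nri
        assert a == pytest.approx(-b)

    def test_symmetric_movers_cancel(self):
        y = np.array([True] * 4 + [False] * 2)
        old = np.array([0.4, 0.6, 0.4, 0.6, 0.4, 0.4])
        new = np.array([0.6, 0.4, 0.6, 0.4, 0.4, 0.4])  # 2 up, 2 down in cases
        assert nri_individual(old, new, y).nri == 0.0


class TestNriNetFromTables:
    def test_identical_tables_zero(self):
        t = ClassificationTable.from_counts([[30, 10], [8, 40]])
        assert nri_net_from_tables(t, t).nri == 0.0

    def test_mismatched_totals_rejected(self):
        a = ClassificationTable.from_counts([[30, 10], [8, 40]])
        b = ClassificationTable.from_counts([[29, 10], [8, 40]])
        with pytest.raises(ValueError):
            nri_net_from_tables(a, b)

    def test_agrees_with_individual_nri_when_movement_unidirectional(self):
        y = np.array([True] * 10 + [False] * 10)
        old = np.where(y, 0.4, 0.6)  # every case below, every control above
        new = old.copy()
        new[:3] = 0.7    # 3 cases cross up
        new[10:12] = 0.3  # 2 controls cross down
        ind = nri_individual(old, new, y)
        from remodelnet.metrics import confusion_at_threshold
        _, _, t_old = confusion_at_threshold(old, y)
        _, _, t_new = confusion_at_threshold(new, y)
        net = nri_net_from_tables(t_old, t_new)
        assert net.nri == pytest.approx(ind.nri)
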