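"""Group comparison, penalized logistic model, ROC/NPV, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

import mcgkit as m
from mcgkit.cohort import PREDICTORS

from .oracles import anova_oneway, auc_all_pairs, elastic_net_logit_cd


def _toy_table(x, y):
    """Wrap a design matrix into the feature-table layout."""
    df = pd.DataFrame(x, columns=list(PREDICTORS)[: x.shape[1]])
    df["is_patient"] = y
    return df


def _fit(table, **kw):
    names = tuple(c for c in table.columns if c != "is_patient")
    return m.fit_penalized_logit(table, feature_names=names, **kw)


class TestCompareGroups:
    def test_f_statistic_matches_hand_anova(self):
        groups = [(1.0, 2.0, 3.0), (2.0, 3.0, 4.0), (3.0, 4.0, 5.0)]
        f_ref, df_b, df_w = anova_oneway(groups)
        assert (f_ref, df_b, df_w) == (3.0, 2, 6)
        table = pd.DataFrame({
            "group": ["A"] * 3 + ["B"] * 3 + ["C"] * 3,
            "QR_peak": np.concatenate(groups),
        })
        out = m.compare_groups(table, predictors=("QR_peak",))
        assert out.loc["QR_peak", "F"] == pytest.approx(3.0)

    def test_type_one_error_calibrated_under_null(self):
        """Identical group distributions rarely get flagged (protected LSD)."""
        rng = np.random.default_rng(99)
        flagged = 0
        reps = 400
        for _ in range(reps):
            table = pd.DataFrame({
                "group": ["A"] * 30 + ["B"] * 30 + ["C"] * 30,
                "QR_peak": rng.normal(40.0, 12.0, size=90),
            })
            out = m.compare_groups(table, predictors=("QR_peak",))
            if any(out.loc["QR_peak", f"sig_{p}"] for p in ("A_vs_B", "A_vs_C", "B_vs_C")):
                flagged += 1
        assert flagged / reps <= 0.06  # no-flag rate >= 94 %

    def test_study_scale_peak_difference_always_detected(self):
        """QR_peak separates patients from young volunteers at study sizes."""
        sc = m.study_scenario()
        hits = 0
        for seed in range(50):
            table = m.sample_feature_cohort(sc, seed=seed)
            sub = table[table.group.isin(["A", "C"])]
            out = m.compare_groups(sub, predictors=("QR_peak",))
            if out.loc["QR_peak", "sig_A_vs_C"]:
                hits += 1
        assert hits >= 50  # > 99 % detection

    def test_degenerate_inputs_rejected(self):
        table = pd.DataFrame({"group": ["A", "A"], "QR_peak": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two groups"):
            m.compare_groups(table, predictors=("QR_peak",))
        flat = pd.DataFrame({
            "group": ["A", "A", "B", "B"],
            "QR_peak": [1.0, 1.0, 1.0, 1.0],
        })
        with pytest.raises(ValueError, match="variance"):
            m.compare_groups(flat, predictors=("QR_peak",))


class TestPenalizedLogit:
    def test_huge_lambda_zeroes_all_coefficients(self, study_table):
        sub = m.make_binary_response(study_table, 1)
        model = m.fit_penalized_logit(sub, alpha=0.3, lambda_rule=1e3)
        assert np.all(model.coef == 0.0)
        base = sub["is_patient"].mean()
        assert model.intercept == pytest.approx(logit(base), abs=1e-3)

    def test_separable_data_reaches_training_auc_one(self, rng):
        x = np.zeros((40, 10))
        x[:, 0] = np.concatenate([rng.normal(-5, 0.1, 20), rng.normal(5, 0.1, 20)])
        x[:, 1:] = rng.normal(size=(40, 9))
        y = np.repeat([0, 1], 20)
        table = _toy_table(x, y)
        model = _fit(table, alpha=0.3, lambda_rule=1e-4)
        probs = m.predict_risk(model, table)
        assert m.roc_auc(probs, y).auc == 1.0

    def test_matches_coordinate_descent_oracle(self, rng):
        """saga solution equals an independent IRLS+CD solver to 1e-4 relative."""
        n, p = 150, 6
        x = rng.normal(size=(n, p))
        eta = 0.8 * x[:, 0] - 1.2 * x[:, 1] + 0.4 * x[:, 2]
        y = (rng.uniform(size=n) < expit(eta)).astype(int)
        table = _toy_table(x, y)
        for alpha, lam in [(0.3, 0.02), (0.3, 0.1), (1.0, 0.05), (0.0, 0.05)]:
            model = _fit(table, alpha=alpha, lambda_rule=lam)
            z = (x - model.standardize_mean) / model.standardize_sd
            b0_ref, b_ref = elastic_net_logit_cd(z, y.astype(float), alpha, lam)
            np.testing.assert_allclose(model.coef, b_ref, rtol=1e-4, atol=1e-6)
            assert model.intercept == pytest.approx(b0_ref, rel=1e-4, abs=1e-6)

    def test_auto_lambda_is_reproducible(self, study_table):
        sub = m.make_binary_response(study_table, 2)
        m1 = m.fit_penalized_logit(sub, seed=3)
        m2 = m.fit_penalized_logit(sub, seed=3)
        assert m1.lam == m2.lam
        np.testing.assert_array_equal(m1.coef, m2.coef)

    def test_single_class_rejected(self, rng):
        table = _toy_table(rng.normal(size=(20, 3)), np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            _fit(table)


class TestPredictRisk:
    def test_null_model_gives_half(self):
        model = m.LogitModel(
            intercept=0.0, coef=np.zeros(2), alpha=0.3, lam=1.0,
            feature_names=("a", "b"),
            standardize_mean=np.zeros(2), standardize_sd=np.ones(2),
        )
        assert m.predict_risk(model, np.array([[3.0, -1.0]]))[0] == pytest.approx(0.5)

    def test_hand_computed_logistic_value(self):
        model = m.LogitModel(
            intercept=-1.0, coef=np.array([2.0]), alpha=0.3, lam=0.0,
            feature_names=("a",),
            standardize_mean=np.zeros(1), standardize_sd=np.ones(1),
        )
        p = m.predict_risk(model, np.array([[1.0]]))[0]
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), abs=1e-12)

    def test_monotone_in_positive_coefficient_feature(self):
        model = m.LogitModel(
            intercept=0.0, coef=np.array([1.5]), alpha=0.3, lam=0.0,
            feature_names=("a",),
            standardize_mean=np.zeros(1), standardize_sd=np.ones(1),
        )
        p = m.predict_risk(model, np.array([[0.0], [1.0], [2.0]]))
        assert np.all(np.diff(p) > 0)

    def test_dimension_mismatch_rejected(self):
        model = m.LogitModel(
            intercept=0.0, coef=np.zeros(3), alpha=0.3, lam=0.0,
            feature_names=("a", "b", "c"),
            standardize_mean=np.zeros(3), standardize_sd=np.ones(3),
        )
        with pytest.raises(ValueError, match="dimension"):
            m.predict_risk(model, np.ones((4, 2)))


class TestRocAuc:
    def test_perfect_and_random_orderings(self):
        y = np.repeat([0, 1], 5)
        assert m.roc_auc(np.arange(10.0), y).auc == 1.0
        assert m.roc_auc(np.full(10, 0.5), y).auc == 0.5

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(0, 4), min_size=8, max_size=16))
    def test_matches_all_pairs_oracle(self, raw):
        """AUC equals brute-force Mann-Whitney pair counting with ties at 1/2."""
        scores = np.asarray(raw, dtype=float) / 4.0
        labels = np.tile([0, 1], len(raw) // 2 + 1)[: len(raw)]
        assert m.roc_auc(scores, labels).auc == pytest.approx(
            auc_all_pairs(scores, labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            m.roc_auc(np.arange(4.0), np.ones(4))


class TestConfusion:
    def test_published_definitions_on_toy_counts(self):
        cm = m.ConfusionCounts(tp=9, fn=1, tn=2, fp=8)
        assert cm.sensitivity == pytest.approx(0.90)
        assert cm.specificity == pytest.approx(0.20)
        assert cm.n == 20

    def test_low_cutoff_classifies_everyone_positive(self, rng):
        probs = rng.uniform(0.1, 0.9, size=50)
        y = rng.integers(0, 2, size=50)
        cm = m.confusion_at_cutoff(probs, y, 0.05)
        assert cm.sensitivity == 1.0 and cm.specificity == 0.0

    def test_counts_match_exhaustive_enumeration(self, rng):
        probs = rng.uniform(size=40)
        y = rng.integers(0, 2, size=40)
        cm = m.confusion_at_cutoff(probs, y, 0.5)
        tp = sum(1 for p, t in zip(probs, y) if p >= 0.5 and t == 1)
        fp = sum(1 for p, t in zip(probs, y) if p >= 0.5 and t == 0)
        tn = sum(1 for p, t in zip(probs, y) if p < 0.5 and t == 0)
        fn = sum(1 for p, t in zip(probs, y) if p < 0.5 and t == 1)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)

    def test_cutoff_bounds_enforced(self):
        with pytest.raises(ValueError):
            m.confusion_at_cutoff(np.array([0.5]), np.array([1]), 0.0)


class TestSelectCutoff:
    def test_returns_largest_qualifying_cutoff(self):
        probs = np.array([0.9, 0.8, 0.6, 0.4, 0.3, 0.2, 0.1, 0.05])
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert m.select_cutoff(probs, labels, min_sensitivity=0.99) == pytest.approx(0.4)

    def test_zero_floor_gives_specificity_maximal_cutoff(self):
        probs = np.array([0.9, 0.8, 0.3, 0.2])
        labels = np.array([1, 0, 1, 0])
        assert m.select_cutoff(probs, labels, min_sensitivity=0.0) == pytest.approx(0.9)

    def test_all_equal_scores_returns_single_candidate(self):
        probs = np.full(6, 0.42)
        labels = np.array([1, 1, 1, 0, 0, 0])
        assert m.select_cutoff(probs, labels) == pytest.approx(0.42)

    def test_unattainable_floor_reports_maximum(self):
        with pytest.raises(ValueError, match="no positive"):
            m.select_cutoff(np.array([0.1, 0.2]), np.array([0, 0]))


class TestNpv:
    def test_rule_out_operating_point(self):
        """The model-1 cross-validated operating point gives 97.7 % NPV."""
        assert 100 * m.npv_from_prevalence(0.954, 0.350, 0.15) == pytest.approx(97.7, abs=0.05)

    def test_direct_evaluation_second_model(self):
        assert 100 * m.npv_from_prevalence(0.913, 0.276, 0.15) == pytest.approx(94.7, abs=0.05)

    def test_perfect_sensitivity_gives_npv_one(self):
        assert m.npv_from_prevalence(1.0, 0.42, 0.15) == 1.0

    @settings(max_examples=60, deadline=None)
    @given(
        sens=st.floats(0.5, 0.999),
        spec=st.floats(0.05, 0.999),
        prev=st.floats(0.01, 0.6),
    )
    def test_monotonicity_properties(self, sens, spec, prev):
        """NPV decreases with prevalence and increases with specificity."""
        base = m.npv_from_prevalence(sens, spec, prev)
        assert m.npv_from_prevalence(sens, spec, min(prev + 0.05, 1.0)) <= base + 1e-12
        assert m.npv_from_prevalence(sens, min(spec + 0.05, 1.0), prev) >= base - 1e-12

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            m.npv_from_prevalence(1.0, 0.0, 0.15)


class TestRepeatedStratifiedCv:
    def test_fold_class_proportions_preserved(self, study_table):
        from sklearn.model_selection import RepeatedStratifiedKFold

        sub = m.make_binary_response(study_table, 1)
        y = sub["is_patient"].to_numpy()
        splitter = RepeatedStratifiedKFold(n_splits=5, n_repeats=2, random_state=0)
        global_pos = y.mean()
        for _, te in splitter.split(np.zeros_like(y), y):
            n_pos = y[te].sum()
            assert abs(n_pos - global_pos * te.size) <= 1.0

    def test_determinism(self, study_table):
        sub = m.make_binary_response(study_table, 3)
        spec = m.CvSpec(folds=5, repeats=2, seed=11)
        r1 = m.repeated_stratified_cv(sub, spec, cutoff=0.3)
        r2 = m.repeated_stratified_cv(sub, spec, cutoff=0.3)
        assert r1[0] == r2[0] and r1[1] == r2[1]

    def test_null_features_give_chance_auc(self, rng):
        """With labels independent of features, CV AUC sits near 0.5."""
        aucs = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            x = r.normal(size=(120, 10))
            y = np.repeat([0, 1], 60)
            table = _toy_table(x, y)
            cv_rep, _ = m.repeated_stratified_cv(
                table, m.CvSpec(folds=5, repeats=2, seed=seed), cutoff=0.6
            )
            aucs.append(cv_rep.auc)
        assert 0.40 < np.mean(aucs) < 0.60

    def test_npv_consistent_with_bayes_formula(self, study_table):
        sub = m.make_binary_response(study_table, 2)
        cv_rep, app = m.repeated_stratified_cv(
            sub, m.CvSpec(folds=5, repeats=2, seed=4), cutoff=0.3
        )
        for rep in (cv_rep, app):
            expected = 100 * m.npv_from_prevalence(
                rep.sensitivity_pct / 100, rep.specificity_pct / 100, rep.prevalence
            )
            assert rep.npv_pct == pytest.approx(expected, abs=1e-9)

    def test_cutoff_selected_per_training_fold(self, study_table):
        """With cutoff=None the sensitivity-floor rule picks the cut-off on
        each training portion; training sensitivity respects the floor while
        held-out sensitivity may shrink below it."""
        sub = m.make_binary_response(study_table, 2)
        cv_rep, app = m.repeated_stratified_cv(
            sub, m.CvSpec(folds=5, repeats=2, seed=2), cutoff=None, min_sensitivity=0.90
        )
        assert 0.0 < app.cutoff < 1.0
        assert app.sensitivity_pct > 90.0  # apparent = selected on the same data
        assert np.isnan(cv_rep.cutoff)  # no single cut-off across folds
        assert 0.0 <= cv_rep.sensitivity_pct <= 100.0

    def test_small_class_rejected(self, rng):
        x = rng.normal(size=(8, 10))
        y = np.array([1, 1, 1, 1, 1, 1, 0, 0])
        with pytest.raises(ValueError, match="stratification"):
            m.repeated_stratified_cv(_toy_table(x, y), m.CvSpec(folds=5, repeats=1, seed=0))

    def test_model_groups(self, study_table):
        sub1 = m.make_binary_response(study_table, 1)
        sub2 = m.make_binary_response(study_table, 2)
        sub3 = m.make_binary_response(study_table, 3)
        assert len(sub1) == 176 and len(sub2) == 139 and len(sub3) == 107
        assert sub1["is_patient"].sum() == 70
        with pytest.raises(ValueError):
            m.make_binary_response(study_table, 4)
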