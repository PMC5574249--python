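import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brcaness import (
    ConfusionMatrix,
    TrialSimConfig,
    ValidationError,
    arm_association,
    characteristics_table,
    combined_subset_or,
    confusion_metrics,
    evaluate_trial,
    interaction_test,
    simulate_trial,
    validate_trial_table,
)
from brcaness.trial import tn_subset_or


def _table(rows):
    df = pd.DataFrame(rows, columns=["arm", "biomarker", "hr_status", "tumor_size_cat", "pcr"])
    df.index = [f"P{i}" for i in range(len(df))]
    return df


def _expand(counts):
    """counts: list of (arm, biomarker, hr, size, pcr, n)."""
    rows = []
    for arm, bio, hr, size, pcr, n in counts:
        rows += [(arm, bio, hr, size, pcr)] * n
    return _table(rows)


@pytest.fixture
def balanced_trial():
    return simulate_trial(TrialSimConfig(seed=3))


class TestConfusionMetrics:
    def test_discovery_set_operating_point(self):
        sens, spec, acc = confusion_metrics(ConfusionMatrix(tp=59, fn=2, fp=18, tn=49))
        assert sens == pytest.approx(0.967, abs=5e-4)
        assert spec == pytest.approx(0.731, abs=5e-4)
        assert acc == pytest.approx(108 / 128)

    def test_perfect_classifier(self):
        sens, spec, acc = confusion_metrics(ConfusionMatrix(tp=10, fn=0, fp=0, tn=10))
        assert (sens, spec, acc) == (1.0, 1.0, 1.0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionMatrix(tp=-1, fn=1, fp=1, tn=1)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValidationError):
            confusion_metrics(ConfusionMatrix(tp=0, fn=0, fp=5, tn=5))


class TestValidateTrialTable:
    def test_valid_table_passes(self, balanced_trial):
        validate_trial_table(balanced_trial)

    def test_missing_column_named(self, balanced_trial):
        with pytest.raises(ValidationError, match="pcr"):
            validate_trial_table(balanced_trial.drop(columns=["pcr"]))

    def test_missing_arm_value_rejected(self, balanced_trial):
        bad = balanced_trial.copy()
        bad.loc[bad.index[0], "arm"] = None
        with pytest.raises(ValidationError, match="arm"):
            validate_trial_table(bad)

    def test_unknown_biomarker_level_rejected(self, balanced_trial):
        bad = balanced_trial.copy()
        bad.loc[bad.index[0], "biomarker"] = "maybe"
        with pytest.raises(ValidationError):
            validate_trial_table(bad)


class TestArmAssociation:
    def test_null_square_table(self):
        t = _expand([
            ("control", "positive", "TN", ">2-5", 1, 10),
            ("control", "positive", "TN", ">2-5", 0, 10),
            ("control", "negative", "HR+", ">2-5", 1, 10),
            ("control", "negative", "HR+", ">2-5", 0, 10),
        ])
        orr, p, counts = arm_association(t, "control")
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)
        np.testing.assert_array_equal(counts, [[10, 10], [10, 10]])

    def test_perfect_association_fisher_p(self):
        t = _expand([
            ("experimental", "positive", "TN", ">2-5", 1, 5),
            ("experimental", "negative", "HR+", ">2-5", 0, 5),
        ])
        orr, p, _ = arm_association(t, "experimental")
        # 2x2 [[5,0],[0,5]]: Fisher two-sided p = 2 / C(10,5) = 1/126
        assert p == pytest.approx(2 / 252)
        # Haldane-Anscombe correction applied because of the zero cells
        assert orr == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))

    def test_cross_product_without_zero_cells(self):
        t = _expand([
            ("control", "positive", "TN", ">2-5", 1, 3),
            ("control", "positive", "TN", ">2-5", 0, 9),
            ("control", "negative", "HR+", ">2-5", 1, 8),
            ("control", "negative", "HR+", ">2-5", 0, 4),
        ])
        orr, _, _ = arm_association(t, "control")
        assert orr == pytest.approx((3 * 4) / (9 * 8))

    def test_fisher_matches_scipy_on_simulated_table(self, balanced_trial):
        orr, p, counts = arm_association(balanced_trial, "experimental")
        _, p_ref = stats.fisher_exact(counts.astype(int))
        assert p == pytest.approx(p_ref)

    def test_absent_arm_named(self, balanced_trial):
        sub = balanced_trial[balanced_trial.arm == "control"]
        with pytest.raises(ValidationError, match="experimental"):
            arm_association(sub, "experimental")


class TestInteractionTest:
    def test_interaction_coefficient_equals_log_or_ratio(self):
        # in the saturated (unadjusted) model the interaction coefficient is
        # exactly log(OR_experimental / OR_control) of the sample tables
        t = _expand([
            ("experimental", "positive", "TN", ">2-5", 1, 12),
            ("experimental", "positive", "TN", ">2-5", 0, 8),
            ("experimental", "negative", "HR+", ">2-5", 1, 5),
            ("experimental", "negative", "HR+", ">2-5", 0, 15),
            ("control", "positive", "TN", ">2-5", 1, 3),
            ("control", "positive", "TN", ">2-5", 0, 17),
            ("control", "negative", "HR+", ">2-5", 1, 7),
            ("control", "negative", "HR+", ">2-5", 0, 13),
        ])
        lr, p, params = interaction_test(t)
        or_exp = (12 * 15) / (8 * 5)
        or_ctrl = (3 * 13) / (17 * 7)
        assert params["arm_x_biomarker"] == pytest.approx(np.log(or_exp / or_ctrl), abs=1e-6)
        assert lr > 0 and 0 < p < 1

    def test_loglik_matches_sklearn_unpenalized(self, balanced_trial):
        sklearn_lm = pytest.importorskip("sklearn.linear_model")
        lr, p, params = interaction_test(balanced_trial, covariates=("hr_status",))
        df = balanced_trial
        X = np.column_stack([
            (df.arm == "experimental").astype(float),
            (df.biomarker == "positive").astype(float),
            ((df.arm == "experimental") & (df.biomarker == "positive")).astype(float),
            (df.hr_status == "TN").astype(float),
        ])
        y = df.pcr.to_numpy()
        clf = sklearn_lm.LogisticRegression(C=np.inf, max_iter=2000, tol=1e-10)
        clf.fit(X, y)
        coef = np.concatenate([clf.intercept_, clf.coef_.ravel()])
        np.testing.assert_allclose(params.to_numpy(), coef, atol=1e-5)

    def test_lr_statistic_against_manual_refit(self, balanced_trial):
        import statsmodels.api as sm

        lr, p, _ = interaction_test(balanced_trial)
        df = balanced_trial
        X = pd.DataFrame({
            "intercept": 1.0,
            "arm": (df.arm == "experimental").astype(float),
            "biomarker": (df.biomarker == "positive").astype(float),
        })
        Xf = X.copy()
        Xf["arm_x_biomarker"] = X["arm"] * X["biomarker"]
        y = df.pcr.astype(float)
        full = sm.Logit(y, Xf).fit(disp=0)
        red = sm.Logit(y, X).fit(disp=0)
        assert lr == pytest.approx(2 * (full.llf - red.llf), abs=1e-6)
        assert p == pytest.approx(stats.chi2.sf(lr, 1))

    def test_size_adjustment_drops_missing_rows_only_when_included(self, balanced_trial):
        t = balanced_trial.copy()
        assert t.tumor_size_cat.isna().any()  # default config has missing sizes
        lr_plain, _, _ = interaction_test(t)
        t_complete = t.dropna(subset=["tumor_size_cat"])
        lr_complete, _, _ = interaction_test(t_complete)
        assert lr_plain != pytest.approx(lr_complete)  # all rows used when size absent
        lr_adj, _, params = interaction_test(t, covariates=("hr_status", "tumor_size_cat"))
        assert any(k.startswith("size_") for k in params.index)

    def test_unknown_covariate_rejected(self, balanced_trial):
        with pytest.raises(ValidationError, match="age"):
            interaction_test(balanced_trial, covariates=("age",))

    def test_degenerate_outcome_rejected(self, balanced_trial):
        t = balanced_trial.copy()
        t["pcr"] = 0
        with pytest.raises(ValidationError):
            interaction_test(t)


class TestCharacteristicsTable:
    def test_reproduces_corrected_and_uncorrected_examples(self):
        # arm x biomarker [[27,17],[34,38]] -> corrected chi2 p ~ 0.198;
        # hr x biomarker [[8,48],[47,13]] -> p << 0.05
        counts = []
        for (arm, bio), n in {("control", "positive"): 27, ("control", "negative"): 17,
                              ("experimental", "positive"): 34, ("experimental", "negative"): 38}.items():
            counts.append((arm, bio, None, None, 0, n))
        rows = []
        for arm, bio, _, _, pcr, n in counts:
            rows += [(arm, bio)] * n
        df = pd.DataFrame(rows, columns=["arm", "biomarker"])
        # assign hr_status to match the HR+ margins: 8/55 of positives, 48/61 of negatives
        hr = []
        pos_seen = neg_seen = 0
        for bio in df.biomarker:
            if bio == "positive":
                hr.append("HR+" if pos_seen < 8 else "TN")
                pos_seen += 1
            else:
                hr.append("HR+" if neg_seen < 48 else "TN")
                neg_seen += 1
        df["hr_status"] = hr
        df["tumor_size_cat"] = ">2-5"
        df["pcr"] = 0
        df.loc[df.index[0], "pcr"] = 1  # avoid degenerate outcome checks downstream
        out = characteristics_table(df)
        assert out.loc["arm", "p"] == pytest.approx(0.198, abs=5e-4)
        assert out.loc["hr_status", "p"] < 1e-10

    def test_corrected_p_matches_scipy(self):
        ct = np.array([[27, 17], [34, 38]])
        res = stats.chi2_contingency(ct, correction=True)
        assert res.pvalue == pytest.approx(0.1976, abs=5e-5)

    def test_single_level_variable_gets_nan(self, balanced_trial):
        t = balanced_trial.copy()
        t["hr_status"] = "TN"
        out = characteristics_table(t)
        assert np.isnan(out.loc["hr_status", "p"])

    def test_size_rows_with_zeros_dropped(self, balanced_trial):
        # default size probabilities put 0 mass on "0-1"; the test must not
        # choke on the empty row
        out = characteristics_table(balanced_trial)
        assert np.isfinite(out.loc["tumor_size_cat", "p"])


class TestSubsetOddsRatios:
    def test_combined_subset_rule_and_gain(self):
        t = _expand([
            # TN patients: in subset regardless of biomarker
            ("experimental", "negative", "TN", ">2-5", 1, 6),
            ("experimental", "negative", "TN", ">2-5", 0, 4),
            ("control", "negative", "TN", ">2-5", 1, 2),
            ("control", "negative", "TN", ">2-5", 0, 8),
            # HR+ biomarker-positive: added by the combined rule
            ("experimental", "positive", "HR+", ">2-5", 1, 3),
            ("experimental", "positive", "HR+", ">2-5", 0, 2),
            ("control", "positive", "HR+", ">2-5", 1, 1),
            ("control", "positive", "HR+", ">2-5", 0, 4),
            # HR+ biomarker-negative: excluded
            ("experimental", "negative", "HR+", ">2-5", 1, 5),
            ("control", "negative", "HR+", ">2-5", 0, 5),
        ])
        orr, gain = combined_subset_or(t)
        # subset 2x2: exp (9 pCR, 6 no), ctrl (3 pCR, 12 no)
        assert orr == pytest.approx((9 * 12) / (6 * 3))
        assert gain == pytest.approx(10 / 40)
        assert tn_subset_or(t) == pytest.approx((6 * 8) / (4 * 2))

    def test_empty_subset_arm_rejected(self):
        t = _expand([
            ("experimental", "negative", "TN", ">2-5", 1, 5),
            ("control", "negative", "HR+", ">2-5", 0, 5),
        ])
        with pytest.raises(ValidationError, match="control"):
            combined_subset_or(t)


class TestEvaluateTrial:
    def test_report_structure_and_consistency(self, balanced_trial):
        report = evaluate_trial(balanced_trial)
        assert set(report["arms"]) == {"control", "experimental"}
        for arm in report["arms"].values():
            assert arm["odds_ratio"] > 0
            assert 0 <= arm["fisher_p"] <= 1
            assert np.asarray(arm["counts"]).shape == (2, 2)
        assert set(report["interaction"]) == {"unadjusted", "hr_adjusted", "hr_size_adjusted"}
        for res in report["interaction"].values():
            assert "p" in res and 0 <= res["p"] <= 1
        # report values agree with the direct function calls
        orr, p, _ = arm_association(balanced_trial, "experimental")
        assert report["arms"]["experimental"]["odds_ratio"] == pytest.approx(orr)
        lr, p_i, _ = interaction_test(balanced_trial, ("hr_status",))
        assert report["interaction"]["hr_adjusted"]["p"] == pytest.approx(p_i)
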