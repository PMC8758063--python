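import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from geoadditive.records import (
    DEFAULT_CODING,
    build_design,
    classify_diabetes,
    classify_hypertension,
    derive_outcomes,
    prevalence_table,
    screen_covariates,
)


class TestClassifyDiabetes:
    @pytest.mark.parametrize("glucose,expected", [(141.0, 1.0), (140.0, 0.0), (85.0, 0.0)])
    def test_strict_threshold(self, glucose, expected):
        # random blood glucose strictly above 140 mg/dl
        assert classify_diabetes(glucose) == expected

    def test_missing_propagates(self):
        assert math.isnan(classify_diabetes(float("nan")))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_diabetes(-5.0)

    def test_idempotent_and_vectorised(self):
        g = np.array([100.0, 141.0, 200.0])
        out = classify_diabetes(g)
        assert np.array_equal(out, [0.0, 1.0, 1.0])


class TestClassifyHypertension:
    def test_first_reading_discarded(self):
        # huge first reading is irrelevant: means over readings 2-3 are 120/80
        assert classify_hypertension([(180, 110), (120, 80), (120, 80)], False) == 0.0

    def test_diastolic_route(self):
        # mean dbp of readings 2-3 is 91 >= 90
        assert classify_hypertension([(160, 100), (145, 92), (143, 90)], False) == 1.0

    def test_medication_overrides_normal_readings(self):
        assert classify_hypertension([(120, 80), (118, 78), (119, 79)], True) == 1.0

    def test_systolic_boundary_inclusive(self):
        assert classify_hypertension([(100, 70), (140, 80), (140, 80)], False) == 1.0

    def test_short_readings_missing(self):
        assert math.isnan(classify_hypertension([(150, 95)], False))
        assert math.isnan(classify_hypertension(None, False))


def test_derive_outcomes_wide_columns_match_rules():
    frame = pd.DataFrame(
        {
            "glucose": [150.0, 120.0, np.nan],
            "sbp1": [180.0, 120.0, 130.0],
            "dbp1": [110.0, 80.0, 85.0],
            "sbp2": [120.0, 150.0, 135.0],
            "dbp2": [80.0, 95.0, 85.0],
            "sbp3": [120.0, 148.0, 137.0],
            "dbp3": [80.0, 93.0, 87.0],
            "on_bp_medication": [False, False, False],
        }
    )
    out = derive_outcomes(frame)
    assert list(out["diabetes"].fillna(-1)) == [1.0, 0.0, -1.0]
    assert list(out["hypertension"]) == [0.0, 1.0, 0.0]


class TestPrevalenceTable:
    @staticmethod
    def _frame(cases_a, n_a, cases_b, n_b):
        lev = ["No"] * n_a + ["Yes"] * n_b
        y = [1.0] * cases_a + [0.0] * (n_a - cases_a) + [1.0] * cases_b + [0.0] * (n_b - cases_b)
        return pd.DataFrame({"consume_milk": lev, "diabetes": y})

    def test_hand_computed_chi_square(self):
        # 10/100 vs 30/100: expected 20 per cell -> chi2 = 12.5, p ~ 4.07e-4
        table, chi2, p = prevalence_table(self._frame(10, 100, 30, 100), "consume_milk", "diabetes")
        assert list(table["prevalence_pct"]) == [10.0, 30.0]
        assert chi2 == pytest.approx(12.5)
        assert p == pytest.approx(0.000407, abs=5e-6)

    def test_identical_rates_give_null_statistic(self):
        _, chi2, p = prevalence_table(self._frame(10, 50, 10, 50), "consume_milk", "diabetes")
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_single_level_p_undefined(self):
        frame = pd.DataFrame({"consume_milk": ["Yes"] * 30, "diabetes": [1.0] * 5 + [0.0] * 25})
        table, chi2, p = prevalence_table(frame, "consume_milk", "diabetes")
        assert len(table) == 1 and math.isnan(p) and math.isnan(chi2)

    def test_prevalences_average_to_overall(self, rng):
        n = 400
        frame = pd.DataFrame(
            {
                "education": rng.choice(DEFAULT_CODING.levels["education"], n),
                "diabetes": rng.random(n) < 0.2,
            }
        )
        frame["diabetes"] = frame["diabetes"].astype(float)
        table, _, _ = prevalence_table(frame, "education", "diabetes")
        overall = (table["prevalence_pct"] * table["n"]).sum() / table["n"].sum()
        assert overall == pytest.approx(100 * frame["diabetes"].mean())
        assert ((table["prevalence_pct"] >= 0) & (table["prevalence_pct"] <= 100)).all()

    def test_matches_permutation_test(self, rng):
        # Monte-Carlo permutation distribution of the chi-square statistic;
        # the mid-p convention handles the discreteness of the n=200 table
        frame = self._frame(40, 100, 50, 100)
        _, chi2, p = prevalence_table(frame, "consume_milk", "diabetes")
        y = frame["diabetes"].to_numpy()
        lev = (frame["consume_milk"] == "Yes").to_numpy()
        n_perm, gt, eq = 4000, 0, 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            tab = np.array(
                [
                    [yp[~lev].sum(), (~lev).sum() - yp[~lev].sum()],
                    [yp[lev].sum(), lev.sum() - yp[lev].sum()],
                ]
            )
            stat = stats.chi2_contingency(tab, correction=False)[0]
            gt += stat > chi2 + 1e-9
            eq += abs(stat - chi2) <= 1e-9
        p_perm = (gt + 0.5 * eq) / n_perm
        assert p == pytest.approx(p_perm, abs=4 * math.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01)


class TestScreening:
    @staticmethod
    def _simulate(rng, n, beta):
        x = rng.random(n) < 0.5
        eta = -1.0 + beta * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return pd.DataFrame({"consume_milk": np.where(x, "Yes", "No"), "diabetes": y})

    def test_strong_effect_retained(self, rng):
        frame = self._simulate(rng, 2000, 1.0)
        selected, detail = screen_covariates(frame, ["consume_milk"], "diabetes")
        assert selected == ["consume_milk"]
        assert (detail["pvalue"] < 0.2).any()

    def test_null_type_one_rate_near_alpha(self, rng):
        hits = 0
        reps = 250
        for _ in range(reps):
            frame = self._simulate(rng, 400, 0.0)
            selected, _ = screen_covariates(frame, ["consume_milk"], "diabetes")
            hits += bool(selected)
        rate = hits / reps
        se = math.sqrt(0.2 * 0.8 / reps)
        assert abs(rate - 0.2) < 4 * se

    def test_empty_candidates(self):
        frame = pd.DataFrame({"diabetes": [0.0, 1.0]})
        selected, detail = screen_covariates(frame, [], "diabetes")
        assert selected == [] and detail.empty

    def test_separation_flagged_and_retained(self, rng, caplog):
        # perfectly separated covariate: Wald p is unusable, must be kept
        frame = pd.DataFrame(
            {"consume_milk": ["Yes"] * 50 + ["No"] * 50, "diabetes": [1.0] * 50 + [0.0] * 50}
        )
        with caplog.at_level("WARNING"):
            selected, _ = screen_covariates(frame, ["consume_milk"], "diabetes")
        assert selected == ["consume_milk"]


class TestBuildDesign:
    def test_reference_coding(self):
        frame = pd.DataFrame(
            {
                "sex": ["Male", "Female"],
                "marital_status": ["Widowed/Divorced/Separated", "Married"],
            }
        )
        X, labels = build_design(frame, ["sex", "marital_status"])
        assert labels == [
            "(Intercept)",
            "sex=Male",
            "marital_status=Married",
            "marital_status=Widowed/Divorced/Separated",
        ]
        assert np.array_equal(X[0], [1.0, 1.0, 0.0, 1.0])  # male, W/D/S -> (0, 1)
        assert np.array_equal(X[1], [1.0, 0.0, 1.0, 0.0])  # reference female carries no column

    def test_unseen_level_raises_with_name(self):
        frame = pd.DataFrame({"sex": ["Male", "Intersex"]})
        with pytest.raises(ValueError, match="Intersex"):
            build_design(frame, ["sex"])
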