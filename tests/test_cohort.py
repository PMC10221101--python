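"""Tests for propensity matching, group tests, strata tests and partial
correlations."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gaitmse.cohort import (
    disability_strata_test,
    dunn_posthoc,
    greedy_match,
    holm_adjust,
    mann_whitney_hedges,
    optimal_match,
    partial_spearman,
    propensity_scores,
    two_group_test,
    cohort_partial_spearman,
)


def make_cohort(ages_p, speeds_p, ages_c, speeds_c, **extra):
    rows = []
    for i, (a, s) in enumerate(zip(ages_p, speeds_p)):
        rows.append({"subject_id": f"P{i}", "trial_id": f"P{i}_T1",
                     "group": "patient", "age": a, "gait_speed": s})
    for i, (a, s) in enumerate(zip(ages_c, speeds_c)):
        rows.append({"subject_id": f"C{i}", "trial_id": f"C{i}_T1",
                     "group": "control", "age": a, "gait_speed": s})
    df = pd.DataFrame(rows)
    for k, v in extra.items():
        df[k] = v
    return df


class TestPropensityScores:
    def test_identical_covariates_give_patient_fraction(self):
        df = make_cohort([70] * 3, [1.1] * 3, [70] * 5, [1.1] * 5)
        ps = propensity_scores(df)
        np.testing.assert_allclose(ps, 3 / 8, atol=1e-6)

    def test_covariate_shift_raises_patient_scores(self):
        rng = np.random.default_rng(0)
        df = make_cohort(
            rng.normal(75, 3, 40), rng.normal(0.9, 0.1, 40),
            rng.normal(65, 3, 40), rng.normal(1.2, 0.1, 40),
        )
        ps = propensity_scores(df)
        assert ps[df.group == "patient"].mean() > ps[df.group == "control"].mean()

    def test_coefficient_signs_recovered_at_large_n(self):
        rng = np.random.default_rng(1)
        n = 2000
        age = rng.normal(70, 5, n)
        speed = rng.normal(1.1, 0.2, n)
        logit = 0.15 * (age - 70) - 3.0 * (speed - 1.1)
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "trial_id": [f"S{i}_T1" for i in range(n)],
            "group": np.where(y, "patient", "control"),
            "age": age, "gait_speed": speed,
        })
        ps = propensity_scores(df)
        const, b_age, b_speed = ps.attrs["coefficients"]
        assert b_age > 0 and b_speed < 0
        assert np.all((ps > 0) & (ps < 1))

    def test_perfect_separation_falls_back_with_warning(self):
        df = make_cohort([80, 81, 82], [1.0, 1.0, 1.0],
                         [60, 61, 62], [1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="separation"):
            ps = propensity_scores(df)
        assert np.all((ps > 0) & (ps < 1))


class TestOptimalMatch:
    def test_worked_two_by_two_example(self):
        res = optimal_match({"p1": 0.30, "p2": 0.40},
                            {"c1": 0.35, "c2": 0.10})
        assert res.total_ps_distance == pytest.approx(0.25)
        assert dict(res.pairs) == {"p2": "c1", "p1": "c2"}
        greedy = greedy_match({"p1": 0.30, "p2": 0.40},
                              {"c1": 0.35, "c2": 0.10})
        assert greedy.total_ps_distance == pytest.approx(0.35)

    def test_identical_scores_any_perfect_matching(self):
        res = optimal_match({f"p{i}": 0.5 for i in range(4)},
                            {f"c{i}": 0.5 for i in range(5)})
        assert res.total_ps_distance == 0.0
        assert len(res.pairs) == 4

    def test_twin_sets_match_exactly(self):
        ps = {"a": 0.2, "b": 0.5, "c": 0.8}
        res = optimal_match(ps, {f"t_{k}": v for k, v in ps.items()})
        assert res.total_ps_distance == 0.0
        assert dict(res.pairs) == {k: f"t_{k}" for k in ps}

    def test_never_worse_than_greedy_with_strict_improvement(self):
        rng = np.random.default_rng(12)
        strict = 0
        for _ in range(100):
            n_p = int(rng.integers(2, 8))
            n_c = int(rng.integers(n_p, 12))
            pats = {f"p{i}": rng.random() for i in range(n_p)}
            cons = {f"c{i}": rng.random() for i in range(n_c)}
            opt = optimal_match(pats, cons).total_ps_distance
            gre = greedy_match(pats, cons).total_ps_distance
            assert opt <= gre + 1e-12
            if opt < gre - 1e-12:
                strict += 1
        assert strict >= 1

    def test_one_trial_per_control_subject(self):
        # one subject owns both closest trials; only one may be used
        res = optimal_match(
            {"p1": 0.30, "p2": 0.31},
            {"s1_a": 0.30, "s1_b": 0.31, "s2_a": 0.90},
            trial_subject={"s1_a": "s1", "s1_b": "s1", "s2_a": "s2"},
        )
        used_subjects = {t.split("_")[0] for _, t in res.pairs}
        assert used_subjects == {"s1", "s2"}

    def test_deficit_error_names_shortfall(self):
        with pytest.raises(ValueError, match="deficit 2"):
            optimal_match({"p1": 0.1, "p2": 0.2, "p3": 0.3}, {"c1": 0.1})


class TestTwoGroupTest:
    def test_hedges_correction_on_small_groups(self):
        res = mann_whitney_hedges([1, 2, 3], [2, 3, 4])
        assert res["cohen_d"] == pytest.approx(-1.0)
        assert res["hedges_g"] == pytest.approx(-0.8)

    def test_identical_groups_null_results(self):
        res = mann_whitney_hedges([1, 2, 3, 4], [1, 2, 3, 4])
        assert res["hedges_g"] == 0.0
        assert res["U"] == pytest.approx(8.0)  # n1*n2/2

    def test_shifted_feature_detected_at_n50(self):
        rng = np.random.default_rng(6)
        a = rng.normal(1.0, 1.0, 50)
        b = rng.normal(0.0, 1.0, 50)
        res = mann_whitney_hedges(a, b)
        assert res["p"] < 0.05
        assert res["hedges_g"] == pytest.approx(1.0, abs=0.45)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0.5, 1, 20), rng.normal(0, 1, 25)
        r1 = mann_whitney_hedges(a, b)
        r2 = mann_whitney_hedges(np.exp(a), np.exp(b))
        assert r1["U"] == r2["U"]
        assert r1["p"] == pytest.approx(r2["p"])

    def test_cohort_wrapper_reports_medians(self):
        df = make_cohort([70] * 3, [1] * 3, [70] * 3, [1] * 3,
                         feat=[1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = two_group_test(df, "feat")
        assert res["median_patient"] == 2.0
        assert res["median_control"] == 5.0


class TestStrataTests:
    def test_identical_strata_are_null(self):
        df = pd.DataFrame({
            "subject_id": [f"P{i}" for i in range(9)],
            "group": "patient",
            "age": 70.0, "gait_speed": 1.0,
            "UPDRS_III": [10, 20, 30, 35, 40, 50, 60, 65, 70],
            "feat": [1, 2, 3] * 3,
        })
        res = disability_strata_test(df, "feat")
        assert res["H"] == pytest.approx(0.0, abs=1e-9)
        assert np.all(res["pairwise"]["p_holm"] == 1.0)

    def test_maximally_separated_strata(self):
        df = pd.DataFrame({
            "subject_id": [f"P{i}" for i in range(9)],
            "group": "patient", "age": 70.0, "gait_speed": 1.0,
            "UPDRS_III": [10] * 3 + [40] * 3 + [60] * 3,
            "feat": [1, 2, 3, 4, 5, 6, 7, 8, 9],
        })
        res = disability_strata_test(df, "feat")
        assert res["H"] == pytest.approx(7.2)
        assert res["strata"] == {"mild": 3, "moderate": 3, "severe": 3}

    def test_empty_stratum_dropped_with_warning(self):
        df = pd.DataFrame({
            "subject_id": [f"P{i}" for i in range(6)],
            "group": "patient", "age": 70.0, "gait_speed": 1.0,
            "UPDRS_III": [10, 15, 20, 40, 45, 50],
            "feat": [1.0, 2, 3, 4, 5, 6],
        })
        with pytest.warns(UserWarning, match="severe"):
            res = disability_strata_test(df, "feat")
        assert len(res["pairwise"]) == 1

    def test_dunn_z_matches_direct_formula_without_ties(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]),
                  np.array([7.0, 8, 9])]
        pw = dunn_posthoc(groups, ["a", "b", "c"])
        # mean ranks 2, 5, 8; var term N(N+1)/12 = 7.5; se = sqrt(7.5*2/3)
        se = math.sqrt(7.5 * (2 / 3))
        row = pw[(pw.group1 == "a") & (pw.group2 == "c")].iloc[0]
        assert row["z"] == pytest.approx(-6.0 / se)

    def test_holm_is_monotone_and_never_below_raw(self):
        raw = np.array([0.01, 0.04, 0.03])
        adj = holm_adjust(raw)
        # step-down: 0.01*3 = 0.03; 0.03*2 = 0.06; cummax keeps 0.04's at 0.06
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06])
        assert np.all(adj >= raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestPartialSpearman:
    def test_no_covariates_equals_spearman(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = partial_spearman(x, y)
        rho, p = stats.spearmanr(x, y)
        assert res["rho_partial"] == pytest.approx(rho, abs=1e-12)
        assert res["p"] == pytest.approx(p, rel=1e-6)

    def test_constant_covariate_equals_spearman(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = partial_spearman(x, y, np.ones((1, 30)))
        rho, _ = stats.spearmanr(x, y)
        assert res["rho_partial"] == pytest.approx(rho, abs=1e-9)

    def test_identity_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        z = rng.normal(size=25)
        res = partial_spearman(x, x, z)
        assert res["rho_partial"] == pytest.approx(1.0)
        assert res["p"] == pytest.approx(0.0, abs=1e-12)

    def test_confounded_correlation_vanishes_after_adjustment(self):
        rng = np.random.default_rng(5)
        n = 500
        z = rng.normal(size=n)
        x = z + 0.5 * rng.normal(size=n)
        y = z + 0.5 * rng.normal(size=n)
        raw = abs(stats.spearmanr(x, y)[0])
        res = partial_spearman(x, y, z)
        assert abs(res["rho_partial"]) < raw
        assert abs(res["rho_partial"]) < 0.1

    def test_agrees_with_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        n = 60
        z = rng.normal(size=n)
        df = pd.DataFrame({
            "x": z + rng.normal(size=n),
            "y": 0.5 * z + rng.normal(size=n),
            "z": z,
        })
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z",
                                    method="spearman")
        res = partial_spearman(df["x"], df["y"], df["z"].to_numpy())
        assert res["rho_partial"] == pytest.approx(float(ref["r"].iloc[0]),
                                                   abs=1e-6)

    def test_cohort_wrapper_drops_missing_rows(self):
        df = make_cohort([70, 71, 72, 73], [1, 1.1, 1.2, 1.3],
                         [70] * 2, [1] * 2)
        df["UPDRS_III"] = [20, 30, 40, 50, np.nan, np.nan]
        df["feat"] = [1.0, 2, 3, 4, 0.5, 0.6]
        res = cohort_partial_spearman(df[df.group == "patient"],
                                      "feat", "UPDRS_III")
        assert res["n"] == 4
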