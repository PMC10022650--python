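from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from lsspanel.panel import (
    WeeklyEffectsEstimator,
    assign_week_index,
    build_panel,
    categorize_participant,
    fit_weekly_fe,
    stratify_and_fit,
)
from lsspanel.synthetic import generate_linear_panel


# ---------------------------------------------------------------------------
# independent oracle: explicit dummy-variable OLS with a hand-built CR1
# clustered sandwich


def dummy_ols_cr1(panel, treatment_year=2020, drop_week_53=True):
    df = panel[panel["week_index"] <= 52] if drop_week_53 else panel
    y = df["lss_score"].to_numpy(float)
    n = len(y)

    def dummies(col, drop_first):
        levels = np.sort(df[col].unique())
        if drop_first:
            levels = levels[1:]
        return np.column_stack([(df[col] == l).to_numpy(float) for l in levels])

    is_treat = (df["year"] == treatment_year).to_numpy()
    treat_weeks = np.sort(df.loc[is_treat, "week_index"].unique())
    T = np.column_stack(
        [(is_treat & (df["week_index"] == w)).to_numpy(float) for w in treat_weeks]
    )
    X = np.column_stack(
        [np.ones(n), dummies("user_id", True), dummies("week_index", True),
         dummies("day_of_week", True), T]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    XtX_inv = np.linalg.inv(X.T @ X)
    groups = df["user_id"].to_numpy()
    meat = np.zeros((X.shape[1], X.shape[1]))
    for g in np.unique(groups):
        m = groups == g
        s = X[m].T @ resid[m]
        meat += np.outer(s, s)
    G = len(np.unique(groups))
    c = (G / (G - 1)) * ((n - 1) / (n - X.shape[1]))
    V = c * XtX_inv @ meat @ XtX_inv
    k0 = X.shape[1] - len(treat_weeks)
    return (
        treat_weeks,
        beta[k0:],
        np.sqrt(np.diag(V)[k0:]),
    )


@pytest.mark.parametrize(
    "day,week",
    [
        ("2020-01-01", 1),
        ("2020-03-02", 9),   # school closure announced/started
        ("2020-04-07", 14),  # state of emergency declared
        ("2020-05-25", 21),  # state of emergency lifted
        ("2020-07-18", 29),  # first celebrity suicide reported
        ("2020-09-27", 39),  # second celebrity suicide reported
        ("2019-12-31", 53),
        ("2020-12-31", 53),
    ],
)
def test_week_index_seven_day_blocks(day, week):
    assert assign_week_index(date.fromisoformat(day)) == week


def test_week_index_vectorized():
    out = assign_week_index(pd.to_datetime(["2020-01-01", "2020-01-08"]))
    assert out.tolist() == [1, 2]


def base_attrs(**overrides):
    rec = {
        "user_id": "u0", "sex": "female", "age_group": "30-39",
        "income_group": "below_6M", "employment": "permanent",
        "phq9_total": 5, "phq9_item9": "not_at_all", "loneliness_total": 4,
    }
    rec.update(overrides)
    return rec


class TestCategorize:
    @pytest.mark.parametrize("phq,expected", [(10, True), (9, False), (27, True), (0, False)])
    def test_depressive_cutoff(self, phq, expected):
        assert categorize_participant(base_attrs(phq9_total=phq))["depressive"] is expected

    @pytest.mark.parametrize("lon,expected", [(6, True), (5, False), (9, True), (3, False)])
    def test_lonely_cutoff(self, lon, expected):
        assert categorize_participant(base_attrs(loneliness_total=lon))["lonely"] is expected

    @pytest.mark.parametrize(
        "item9,expected",
        [("not_at_all", False), ("several_days", True),
         ("more_than_half", True), ("nearly_every_day", True)],
    )
    def test_suicidal_from_item9(self, item9, expected):
        assert categorize_participant(base_attrs(phq9_item9=item9))["suicidal"] is expected

    def test_excluded_flags(self):
        rec = categorize_participant(base_attrs(sex="other/NA", employment="other/NA"))
        assert rec["excluded_sex"] and rec["excluded_employment"]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            categorize_participant(base_attrs(phq9_total=30))
        with pytest.raises(ValueError):
            categorize_participant(base_attrs(loneliness_total=2))
        with pytest.raises(ValueError):
            categorize_participant(base_attrs(phq9_item9="sometimes"))


def scored_frame(rows):
    return pd.DataFrame(rows, columns=["doc_id", "user_id", "timestamp", "lss_score"])


class TestBuildPanel:
    def attrs_table(self, users):
        return pd.DataFrame([base_attrs(user_id=u) for u in users])

    def test_counting(self):
        rows = []
        i = 0
        for user in ("u0", "u1"):
            for year in (2019, 2020):
                for w in range(3):
                    rows.append((f"d{i}", user, date(year, 1, 2) + timedelta(weeks=w), 0.1))
                    i += 1
        panel = build_panel(scored_frame(rows), self.attrs_table(["u0", "u1"]))
        assert len(panel) == 12
        assert set(panel["week_index"]) == {1, 2, 3}

    def test_out_of_window_and_unscored_dropped(self):
        rows = [
            ("d0", "u0", date(2019, 5, 1), 0.2),
            ("d1", "u0", date(2018, 5, 1), 0.2),
            ("d2", "u0", date(2020, 5, 1), np.nan),
        ]
        panel = build_panel(scored_frame(rows), self.attrs_table(["u0"]))
        assert len(panel) == 1
        assert panel.attrs["n_outside_window"] == 1
        assert panel.attrs["n_unscored_dropped"] == 1

    def test_missing_attributes_error(self):
        rows = [("d0", "ghost", date(2019, 5, 1), 0.2)]
        with pytest.raises(ValueError, match="ghost"):
            build_panel(scored_frame(rows), self.attrs_table(["u0"]))

    def test_row_count_matches_recount(self, small_study, small_scored):
        _, scores = small_scored
        panel = build_panel(scores, small_study.attributes)
        in_window = pd.to_datetime(scores["timestamp"]).dt.year.isin([2019, 2020])
        expected = int((scores["lss_score"].notna() & in_window).sum())
        assert len(panel) == expected


def null_panel():
    """Treatment-year observations mirror baseline-year observations exactly
    (same user, week, day-of-week and score)."""
    rows = []
    i = 0
    for year in (2019, 2020):
        for u in range(4):
            for w in range(1, 9):
                for dow in (0, 3):
                    day = date(year, 1, 1) + timedelta(days=(w - 1) * 7 + dow)
                    score = 0.3 * u - 0.1 * w + 0.05 * dow + 0.2 * u * w
                    rows.append((f"u{u}", f"d{i}", pd.Timestamp(day), year, w,
                                 dow, score))
                    i += 1
    panel = pd.DataFrame(rows, columns=["user_id", "doc_id", "date", "year",
                                        "week_index", "day_of_week", "lss_score"])
    panel.attrs["treatment_year"] = 2020
    return panel


class TestWeeklyFixedEffects:
    def test_null_effect_exactly_zero(self):
        est = fit_weekly_fe(null_panel())
        assert np.abs(est["delta"].to_numpy()).max() < 1e-10

    def test_user_shift_absorbed(self):
        panel = generate_linear_panel(n_users=6, weeks=6, random_seed=4)
        base = fit_weekly_fe(panel)
        shifted = panel.copy()
        mask = shifted["user_id"] == "u001"
        shifted.loc[mask, "lss_score"] += 5.0
        est = fit_weekly_fe(shifted)
        assert est["delta"].to_numpy() == pytest.approx(base["delta"].to_numpy(), abs=1e-8)

    def test_treatment_week_shift_adds_exactly(self):
        panel = generate_linear_panel(n_users=6, weeks=6, random_seed=4)
        base = fit_weekly_fe(panel)
        shifted = panel.copy()
        mask = (shifted["year"] == 2020) & (shifted["week_index"] == 3)
        shifted.loc[mask, "lss_score"] += 0.7
        est = fit_weekly_fe(shifted)
        diff = est.set_index("week")["delta"] - base.set_index("week")["delta"]
        assert diff[3] == pytest.approx(0.7, abs=1e-8)
        assert diff.drop(3).abs().max() < 1e-8

    def test_week_of_year_shift_absorbed(self):
        panel = generate_linear_panel(n_users=6, weeks=6, random_seed=4)
        base = fit_weekly_fe(panel)
        shifted = panel.copy()
        mask = shifted["week_index"] == 2  # both years: pure seasonality
        shifted.loc[mask, "lss_score"] += 1.3
        est = fit_weekly_fe(shifted)
        assert est["delta"].to_numpy() == pytest.approx(base["delta"].to_numpy(), abs=1e-8)

    def test_matches_explicit_dummy_oracle(self):
        panel = generate_linear_panel(n_users=5, weeks=8, docs_per_cell=3,
                                      delta={3: 0.4, 4: -0.2}, random_seed=9)
        assert len(panel) <= 1000
        est = fit_weekly_fe(panel)
        weeks, delta, se = dummy_ols_cr1(panel)
        assert est["week"].to_numpy().tolist() == weeks.tolist()
        assert est["delta"].to_numpy() == pytest.approx(delta, abs=1e-8)
        assert est["se"].to_numpy() == pytest.approx(se, abs=1e-8)

    def test_matches_statsmodels_clustered(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        panel = generate_linear_panel(n_users=5, weeks=5, docs_per_cell=2,
                                      delta={2: 0.5}, random_seed=3)
        est = fit_weekly_fe(panel).set_index("week")
        df = panel.copy()
        for w in sorted(df.loc[df["year"] == 2020, "week_index"].unique()):
            df[f"tw{w}"] = ((df["year"] == 2020) & (df["week_index"] == w)).astype(float)
        formula = ("lss_score ~ C(user_id) + C(week_index) + C(day_of_week) + "
                   + " + ".join(f"tw{w}" for w in range(1, 6)))
        res = smf.ols(formula, data=df).fit(
            cov_type="cluster", cov_kwds={"groups": df["user_id"]}
        )
        for w in range(1, 6):
            assert res.params[f"tw{w}"] == pytest.approx(est.loc[w, "delta"], abs=1e-8)
            assert res.bse[f"tw{w}"] == pytest.approx(est.loc[w, "se"], abs=1e-6)

    def test_ci_uses_normal_critical_value(self):
        panel = generate_linear_panel(n_users=6, weeks=4, random_seed=1)
        est = fit_weekly_fe(panel)
        assert est["ci_high"].to_numpy() == pytest.approx(
            (est["delta"] + 1.96 * est["se"]).to_numpy()
        )

    def test_single_year_rejected(self):
        panel = generate_linear_panel(n_users=4, weeks=4, random_seed=0)
        with pytest.raises(ValueError, match="both"):
            fit_weekly_fe(panel[panel["year"] == 2019])

    def test_week53_excluded(self):
        panel = generate_linear_panel(n_users=4, weeks=4, random_seed=0)
        extra = panel.iloc[:4].copy()
        extra["week_index"] = 53
        extra["doc_id"] = [f"x{i}" for i in range(4)]
        est_a = fit_weekly_fe(panel)
        est_b = fit_weekly_fe(pd.concat([panel, extra], ignore_index=True))
        assert 53 not in est_b["week"].tolist()
        assert est_b["delta"].to_numpy() == pytest.approx(est_a["delta"].to_numpy())


class TestStratify:
    def with_group(self, panel, value):
        panel = panel.copy()
        panel["depressive"] = value
        return panel

    def test_single_group_equals_pooled(self):
        panel = self.with_group(
            generate_linear_panel(n_users=5, weeks=5, delta={2: 0.3}, random_seed=2), True
        )
        pooled = fit_weekly_fe(panel)
        per_group = stratify_and_fit(panel, "depressive")
        assert list(per_group) == ["True"]
        got = per_group["True"].drop(columns="group")
        pd.testing.assert_frame_equal(got, pooled)

    def test_planted_subgroup_effect(self):
        affected = self.with_group(
            generate_linear_panel(n_users=20, weeks=8, docs_per_cell=4,
                                  delta={4: 0.3}, random_seed=21), True
        )
        unaffected = self.with_group(
            generate_linear_panel(n_users=20, weeks=8, docs_per_cell=4,
                                  delta={}, random_seed=22), False
        )
        unaffected = unaffected.assign(
            user_id="x" + unaffected["user_id"],
            doc_id="x" + unaffected["doc_id"],
        )
        panel = pd.concat([affected, unaffected], ignore_index=True)
        panel.attrs["treatment_year"] = 2020
        per_group = stratify_and_fit(panel, "depressive")
        d_yes = per_group["True"].set_index("week").loc[4, "delta"]
        d_no = per_group["False"].set_index("week").loc[4, "delta"]
        assert d_yes == pytest.approx(0.3, abs=0.1)
        assert abs(d_no) < 0.1

    def test_partition_counts(self):
        panel = generate_linear_panel(n_users=8, weeks=4, random_seed=5)
        panel["sex"] = np.where(panel["user_id"] < "u004", "female", "male")
        panel["excluded_sex"] = panel["user_id"] == "u007"
        per_group = stratify_and_fit(panel, "sex")
        n_excluded = int(panel["excluded_sex"].sum())
        total = sum(
            WeeklyEffectsEstimator().fit(panel[(panel["sex"] == g) & ~panel["excluded_sex"]]).n_obs_
            for g in ("female", "male")
        )
        assert total == len(panel) - n_excluded
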