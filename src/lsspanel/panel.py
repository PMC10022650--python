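"""Participant panel construction and two-way fixed-effects estimation.

The design compares each week of a treatment year (e.g. 2020) with the
matched week of a baseline year (e.g. 2019) within person.  Individual
document scores are regressed on treatment-year weekly indicators while
absorbing person, week-of-year and day-of-week fixed effects, so each weekly
coefficient δ_τ is the deviation of that treatment week from the same
calendar week in the baseline year, net of stable individual differences and
calendar seasonality.  Standard errors are clustered by participant
(CR1 small-sample adjustment) since a person's documents are serially
dependent.

Weeks are consecutive 7-day blocks counted from January 1 (week 1 = Jan
1-7), so "week 9" of 2020 is Feb 26 - Mar 3.  Block 53 (days 365-366) is a
partial week and is excluded from estimation.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

__all__ = [
    "assign_week_index",
    "categorize_participant",
    "build_panel",
    "WeeklyEffectsEstimator",
    "fit_weekly_fe",
    "stratify_and_fit",
]

PHQ9_ITEM9_LEVELS = ("not_at_all", "several_days", "more_than_half", "nearly_every_day")
#: attribute values flagging a participant out of the matching stratified run
EXCLUDED_LEVEL = "other/NA"


def assign_week_index(dates):
    """Week of the year as consecutive 7-day blocks from January 1.

    week = floor((day_of_year - 1) / 7) + 1, in 1..53 (block 53 holds days
    365-366).  Accepts a single date or an array-like; vectorized via pandas.
    """
    import datetime as _dt

    scalar = isinstance(dates, (str, _dt.date, _dt.datetime, pd.Timestamp, np.datetime64))
    idx = pd.DatetimeIndex(pd.to_datetime([dates] if scalar else dates))
    weeks = (idx.dayofyear - 1) // 7 + 1
    return int(weeks[0]) if scalar else np.asarray(weeks)


def categorize_participant(attributes):
    """Derive analysis group labels from survey measures.

    depressive: PHQ-9 total >= 10; lonely: 3-item loneliness total >= 6;
    suicidal: PHQ-9 item 9 answered anything other than "not at all".
    Income, employment and age groups are copied through.  Participants with
    sex or employment recorded as ``other/NA`` keep their rows but are
    flagged for exclusion from the corresponding stratified runs.

    Accepts a single mapping or a DataFrame; returns the same kind with the
    derived columns added.
    """
    single = isinstance(attributes, Mapping)
    df = pd.DataFrame([attributes]) if single else attributes.copy()

    phq = df["phq9_total"].to_numpy()
    lon = df["loneliness_total"].to_numpy()
    if ((phq < 0) | (phq > 27)).any():
        raise ValueError("phq9_total outside 0..27")
    if ((lon < 3) | (lon > 9)).any():
        raise ValueError("loneliness_total outside 3..9")
    bad_item9 = set(df["phq9_item9"]) - set(PHQ9_ITEM9_LEVELS)
    if bad_item9:
        raise ValueError(f"unknown phq9_item9 level(s): {sorted(bad_item9)}")

    df["depressive"] = phq >= 10
    df["lonely"] = lon >= 6
    df["suicidal"] = (df["phq9_item9"] != "not_at_all").to_numpy()
    df["excluded_sex"] = (df["sex"] == EXCLUDED_LEVEL).to_numpy()
    df["excluded_employment"] = (df["employment"] == EXCLUDED_LEVEL).to_numpy()
    return df.iloc[0].to_dict() if single else df


def build_panel(
    scored_documents: pd.DataFrame,
    attributes: pd.DataFrame,
    baseline_year: int = 2019,
    treatment_year: int = 2020,
) -> pd.DataFrame:
    """Join scored documents to participant attributes and calendar indices.

    Keeps only documents with a defined score whose date falls in the
    baseline or treatment year.  Every retained document's author must
    appear in ``attributes`` (error otherwise).  ``attrs`` records the
    number of unscored and out-of-window documents dropped.
    """
    df = scored_documents.copy()
    ts = pd.to_datetime(df["timestamp"])
    df["date"] = ts.dt.normalize()
    n_unscored = int(df["lss_score"].isna().sum())
    df = df[df["lss_score"].notna()]
    df["year"] = df["date"].dt.year
    in_window = df["year"].isin([baseline_year, treatment_year])
    n_outside = int((~in_window).sum())
    df = df[in_window].copy()
    df["week_index"] = assign_week_index(df["date"])
    df["day_of_week"] = df["date"].dt.dayofweek

    attr = categorize_participant(attributes) if "depressive" not in attributes else attributes
    missing = sorted(set(df["user_id"]) - set(attr["user_id"]))
    if missing:
        raise ValueError(f"users without attributes: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    cols = ["user_id", "doc_id", "date", "year", "week_index", "day_of_week", "lss_score"]
    panel = df[cols].merge(attr, on="user_id", how="left")
    panel.attrs["n_unscored_dropped"] = n_unscored
    panel.attrs["n_outside_window"] = n_outside
    panel.attrs["baseline_year"] = baseline_year
    panel.attrs["treatment_year"] = treatment_year
    return panel.reset_index(drop=True)


def _group_demean(M: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    G = sp.csr_matrix(
        (np.ones(len(codes)), (codes, np.arange(len(codes)))),
        shape=(n_groups, len(codes)),
    )
    means = (G @ M) / counts[:, None]
    return M - means[codes]


class WeeklyEffectsEstimator(BaseEstimator):
    """Two-way (three-factor) fixed-effects event-study regression.

    OLS of the document score on treatment-year weekly indicators with
    person, week-of-year and day-of-week fixed effects absorbed by
    alternating-projection demeaning (Frisch-Waugh), and CR1 cluster-robust
    standard errors with clusters = participants.  95% CIs use the normal
    critical value.

    Parameters
    ----------
    treatment_year : int or None
        Year whose weekly deviations are estimated; taken from the panel's
        ``attrs`` when None.
    outcome, cluster : column names.
    drop_week_53 : exclude the partial 7-day block 53 from estimation.
    z : CI critical value (1.96).

    Attributes (after fit)
    ----------------------
    effects_ : DataFrame (week, delta, se, ci_low, ci_high, n_obs, n_clusters)
    n_obs_, n_clusters_ : estimation-sample sizes
    dropped_weeks_ : treatment weeks dropped for collinearity (absorbed)
    """

    def __init__(
        self,
        treatment_year: int | None = None,
        outcome: str = "lss_score",
        cluster: str = "user_id",
        drop_week_53: bool = True,
        z: float = 1.96,
        tol: float = 1e-12,
        max_iter: int = 2000,
    ):
        self.treatment_year = treatment_year
        self.outcome = outcome
        self.cluster = cluster
        self.drop_week_53 = drop_week_53
        self.z = z
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, panel: pd.DataFrame, y=None) -> "WeeklyEffectsEstimator":
        treatment_year = self.treatment_year
        if treatment_year is None:
            treatment_year = panel.attrs.get("treatment_year")
        if treatment_year is None:
            raise ValueError("treatment_year not given and absent from panel attrs")
        df = panel
        if self.drop_week_53:
            df = df[df["week_index"] <= 52]
        if df["year"].nunique() < 2:
            raise ValueError("panel must contain both baseline and treatment years")

        yv = df[self.outcome].to_numpy(dtype=float)
        n = len(yv)
        users, user_codes = np.unique(df[self.cluster].to_numpy(), return_inverse=True)
        if len(users) < 2:
            raise ValueError("need at least 2 clusters")
        _, woy_codes = np.unique(df["week_index"].to_numpy(), return_inverse=True)
        _, dow_codes = np.unique(df["day_of_week"].to_numpy(), return_inverse=True)

        is_treat = (df["year"] == treatment_year).to_numpy()
        treat_weeks = np.sort(np.unique(df.loc[is_treat, "week_index"]))
        T = np.zeros((n, len(treat_weeks)))
        for j, w in enumerate(treat_weeks):
            T[:, j] = is_treat & (df["week_index"].to_numpy() == w)

        # Alternating projections: demean outcome + treatment dummies on the
        # three fixed-effect factors until numerically converged.
        M = np.column_stack([yv, T])
        factors = [
            (user_codes, len(users)),
            (woy_codes, woy_codes.max() + 1),
            (dow_codes, dow_codes.max() + 1),
        ]
        scale0 = max(float(np.abs(M).max()), 1.0)
        for _ in range(self.max_iter):
            before = M.copy()
            for codes, n_groups in factors:
                M = _group_demean(M, codes, n_groups)
            if np.abs(M - before).max() <= self.tol * scale0:
                break
        else:
            warnings.warn("fixed-effect demeaning did not fully converge", stacklevel=2)

        yt, Xt = M[:, 0], M[:, 1:]

        # Treatment dummies fully absorbed by the fixed effects carry no
        # information; drop them and report the weeks as absent.
        col_norm = (Xt**2).sum(axis=0)
        keep = col_norm > 1e-8 * n
        dropped = [int(w) for w, k in zip(treat_weeks, keep) if not k]
        if dropped:
            warnings.warn(f"treatment week dummies absorbed/collinear, dropped: {dropped}",
                          stacklevel=2)
        Xk = Xt[:, keep]
        kept_weeks = treat_weeks[keep]

        XtX = Xk.T @ Xk
        try:
            beta = np.linalg.solve(XtX, Xk.T @ yt)
            XtX_inv = np.linalg.inv(XtX)
        except np.linalg.LinAlgError:
            warnings.warn("collinearity among demeaned treatment dummies; using pseudoinverse",
                          stacklevel=2)
            XtX_inv = np.linalg.pinv(XtX)
            beta = XtX_inv @ (Xk.T @ yt)
        resid = yt - Xk @ beta

        # CR1 sandwich; K counts all parameters of the equivalent explicit-
        # dummy regression (absorbed effects included) so the small-sample
        # correction matches it exactly.
        G = len(users)
        cluster_sizes = np.bincount(user_codes, minlength=G)
        if (cluster_sizes == 1).any():
            warnings.warn("singleton cluster(s) present", stacklevel=2)
        S = sp.csr_matrix(
            (np.ones(n), (user_codes, np.arange(n))), shape=(G, n)
        )
        scores = S @ (Xk * resid[:, None])  # (G, k) cluster score sums
        meat = scores.T @ scores
        k_params = (
            Xk.shape[1]
            + (len(users) - 1)
            + (len(np.unique(woy_codes)) - 1)
            + (len(np.unique(dow_codes)) - 1)
            + 1
        )
        c = (G / (G - 1)) * ((n - 1) / (n - k_params))
        V = c * XtX_inv @ meat @ XtX_inv
        se = np.sqrt(np.diag(V))

        n_obs_week = {
            int(w): int((is_treat & (df["week_index"].to_numpy() == w)).sum())
            for w in kept_weeks
        }
        self.effects_ = pd.DataFrame(
            {
                "week": kept_weeks.astype(int),
                "delta": beta,
                "se": se,
                "ci_low": beta - self.z * se,
                "ci_high": beta + self.z * se,
                "n_obs": [n_obs_week[int(w)] for w in kept_weeks],
                "n_clusters": G,
            }
        )
        self.vcov_ = V
        self.n_obs_ = n
        self.n_clusters_ = G
        self.dropped_weeks_ = dropped
        return self


def fit_weekly_fe(panel: pd.DataFrame, **config) -> pd.DataFrame:
    """Fit the weekly fixed-effects model; returns the effects table."""
    return WeeklyEffectsEstimator(**config).fit(panel).effects_


def stratify_and_fit(
    panel: pd.DataFrame, group_field: str, **config
) -> dict[str, pd.DataFrame]:
    """Fit the weekly model separately within each level of ``group_field``.

    Participants flagged ``other/NA`` on the stratifying variable (sex,
    employment) are omitted from that stratification, mirroring the survey
    exclusions.  Empty or degenerate subgroups are reported absent.
    """
    df = panel
    flag = {"sex": "excluded_sex", "employment": "excluded_employment"}.get(group_field)
    if flag is not None and flag in df.columns:
        df = df[~df[flag]]
    out: dict[str, pd.DataFrame] = {}
    for level, sub in df.groupby(group_field, sort=True):
        try:
            est = WeeklyEffectsEstimator(**config).fit(sub)
        except ValueError as err:
            warnings.warn(f"subgroup {group_field}={level!r} skipped: {err}", stacklevel=2)
            continue
        eff = est.effects_.copy()
        eff["group"] = level
        out[str(level)] = eff
    return out
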