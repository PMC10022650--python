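"""Descriptive distress trajectories.

Complements the regression analysis with model-light descriptions: each
document's score is expressed as a deviation from its author's baseline-year
mean, the pooled deviations are smoothed with a local-linear (loess)
regression over a rolling window holding a fixed fraction of the data, and
weekly means are tabulated alongside exogenous series such as weekly news
or case counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panel import assign_week_index

__all__ = ["baseline_deviation", "loess_smooth", "weekly_aggregate"]


def baseline_deviation(
    scored_documents: pd.DataFrame, baseline_year: int = 2019
) -> pd.DataFrame:
    """Score deviations from each user's baseline-year mean.

    Users without any scored baseline-year document cannot be centered and
    are dropped; ``attrs["n_users_dropped"]`` counts them.
    """
    df = scored_documents[scored_documents["lss_score"].notna()].copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    base = df[df["date"].dt.year == baseline_year]
    user_means = base.groupby("user_id")["lss_score"].mean()
    n_users = df["user_id"].nunique()
    df = df[df["user_id"].isin(user_means.index)].copy()
    df["deviation"] = df["lss_score"].to_numpy() - user_means[df["user_id"]].to_numpy()
    df.attrs["n_users_dropped"] = int(n_users - len(user_means))
    return df.reset_index(drop=True)


def loess_smooth(
    times,
    values,
    span_fraction: float = 0.05,
    grid=None,
    z: float = 1.96,
) -> pd.DataFrame:
    """Locally weighted linear regression over the rolling ``span_fraction``
    of points, with pointwise normal-theory 95% CI bands.

    At each grid point the nearest ceil(span * n) observations get tricube
    weights by distance; a weighted line is fit and evaluated there.  The CI
    uses the local weighted-least-squares prediction variance with the local
    residual variance, assuming independent errors.  ``times`` may be
    datetimes (converted to days) or numbers; the default grid is daily
    (unit-spaced) across the observed range.

    Returns a DataFrame (time, mean, ci_low, ci_high) with time strictly
    increasing.
    """
    t = np.asarray(times)
    if np.issubdtype(t.dtype, np.datetime64) or isinstance(
        times, (pd.Series, pd.DatetimeIndex)
    ):
        ts = pd.to_datetime(t)
        t0 = ts.min()
        tnum = (ts - t0) / pd.Timedelta(days=1)
        tnum = np.asarray(tnum, dtype=float)
        to_time = lambda x: t0 + pd.to_timedelta(x, unit="D")  # noqa: E731
    else:
        tnum = np.asarray(t, dtype=float)
        to_time = lambda x: x  # noqa: E731
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    tnum, v = tnum[ok], v[ok]
    n = len(v)
    if n < 20:
        raise ValueError("need at least 20 points to smooth")
    order = np.argsort(tnum, kind="stable")
    tnum, v = tnum[order], v[order]

    k = max(int(np.ceil(span_fraction * n)), 1)
    if k < 3:
        warnings.warn("span window below local rank; widening to 3 points", stacklevel=2)
        k = 3
    if grid is None:
        grid = np.arange(np.floor(tnum[0]), np.ceil(tnum[-1]) + 1.0)
    else:
        grid = np.asarray(grid, dtype=float)

    means = np.empty(len(grid))
    ses = np.empty(len(grid))
    for i, g in enumerate(grid):
        # nearest-k window via the sorted times
        lo = np.searchsorted(tnum, g)
        a, b = max(0, lo - k), min(n, lo + k)
        window = np.arange(a, b)
        d = np.abs(tnum[window] - g)
        cut = np.partition(d, k - 1)[k - 1] if len(d) > k else d.max()
        sel = window[d <= cut]
        x = tnum[sel] - g
        yw = v[sel]
        h = max(np.abs(x).max(), 1e-12)
        w = (1 - np.minimum(np.abs(x) / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-12)
        X = np.column_stack([np.ones(len(x)), x])
        W = w
        XtWX = X.T @ (X * W[:, None])
        XtWy = X.T @ (W * yw)
        try:
            coef = np.linalg.solve(XtWX, XtWy)
            XtWX_inv = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            XtWX_inv = np.linalg.pinv(XtWX)
            coef = XtWX_inv @ XtWy
        resid = yw - X @ coef
        dof = max(len(x) - 2, 1)
        sigma2 = float((W * resid**2).sum() / (W.sum() * dof / len(x)))
        # prediction variance at x=0: e1' A^{-1} X'W^2X A^{-1} e1 * sigma2
        B = X.T @ (X * (W**2)[:, None])
        var = float((XtWX_inv @ B @ XtWX_inv)[0, 0]) * sigma2
        means[i] = coef[0]
        ses[i] = np.sqrt(max(var, 0.0))

    return pd.DataFrame(
        {
            "time": [to_time(g) for g in grid],
            "mean": means,
            "ci_low": means - z * ses,
            "ci_high": means + z * ses,
        }
    )


def weekly_aggregate(
    scored_documents: pd.DataFrame,
    exogenous: dict[str, pd.DataFrame] | None = None,
    year: int | None = None,
    score_column: str = "lss_score",
) -> pd.DataFrame:
    """Weekly mean score and document count, joined to exogenous series.

    ``exogenous`` maps a column name (e.g. ``news_count``) to a DataFrame
    with a ``week`` (or ``date``) column and a value column of the same
    name.  The join is outer so weeks present on one side only are kept with
    missing values.  ``attrs["correlations"]`` holds the Pearson correlation
    between the weekly mean score and each exogenous series over the weeks
    where both are present.
    """
    df = scored_documents[scored_documents[score_column].notna()].copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    if year is not None:
        df = df[df["date"].dt.year == year]
    df["week_index"] = assign_week_index(df["date"])
    weekly = (
        df.groupby("week_index")[score_column]
        .agg(mean_lss="mean", n_docs="size")
        .reset_index()
        .rename(columns={"week_index": "week"})
    )

    correlations: dict[str, float] = {}
    if exogenous:
        for name, table in exogenous.items():
            tab = table.copy()
            if "week" not in tab.columns:
                tab["week"] = assign_week_index(pd.to_datetime(tab["date"]))
                tab = tab.groupby("week", as_index=False)[name].sum()
            tab = tab[["week", name]]
            weekly = weekly.merge(tab, on="week", how="outer")
        weekly = weekly.sort_values("week").reset_index(drop=True)
        for name in exogenous:
            both = weekly.dropna(subset=["mean_lss", name])
            if len(both) >= 3 and both[name].std() > 0 and both["mean_lss"].std() > 0:
                correlations[name] = float(
                    np.corrcoef(both["mean_lss"], both[name])[0, 1]
                )
            else:
                correlations[name] = float("nan")
    weekly.attrs["correlations"] = correlations
    return weekly
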