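"""Daily URL-share counts per source group and baseline-adjusted OLS trends.

The trend model regresses a group's daily URL count on the day index and on
the same-day count of the random-baseline group:

    V_C ~ t*beta_t + V_R*beta_baseline        (conspiracy; V_Q analogous)

so beta_t is the daily growth in unreliable-URL volume *adjusted for* the
overall growth of URL sharing on the platform. The intercept is off by
default, matching the model as written; ``include_intercept=True`` adds
one. Inference is classical OLS (t-distribution, n − p degrees of freedom).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import timedelta

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import SourceGroup, TweetRecord, url_to_domain
from .subset import VolumeSeries, _week_start, trailing_mean

__all__ = ["TrendFit", "daily_counts", "fit_trend", "weekly_share_curve"]


@dataclass(frozen=True)
class TrendFit:
    group: str
    beta_t: float
    beta_baseline: float
    intercept: float | None
    se: dict
    pvalues: dict
    conf_int: dict   # 95% CIs, name -> (lo, hi)
    n_days: int

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "beta_t": self.beta_t,
            "beta_baseline": self.beta_baseline,
            "intercept": self.intercept,
            "se": self.se,
            "pvalues": self.pvalues,
            "conf_int": {k: list(v) for k, v in self.conf_int.items()},
            "n_days": self.n_days,
        }


def daily_counts(
    tweets: list[TweetRecord], groups: list[SourceGroup]
) -> pd.DataFrame:
    """Per-day URL-share counts for each group (each URL occurrence counts
    once); index is the full observed day span with zeros filled."""
    membership = {g.name: g.domains for g in groups}
    rows: dict = {}
    for tw in tweets:
        day = tw.timestamp.date()
        row = rows.setdefault(day, dict.fromkeys(membership, 0))
        for url in tw.urls:
            dom = url_to_domain(url)
            if dom is None:
                continue
            for name, doms in membership.items():
                if dom in doms:
                    row[name] += 1
    if not rows:
        return pd.DataFrame(columns=list(membership))
    lo, hi = min(rows), max(rows)
    days = [lo + timedelta(days=i) for i in range((hi - lo).days + 1)]
    df = pd.DataFrame(
        [rows.get(d, dict.fromkeys(membership, 0)) for d in days],
        index=pd.Index(days, name="date"),
    )
    return df


def fit_trend(
    counts: pd.DataFrame,
    group: str,
    baseline: str = "random",
    include_intercept: bool = False,
) -> TrendFit:
    """OLS of the group's daily count on (day index, baseline count).

    Day index starts at 0 on the first observed day. Raises on constant or
    collinear regressors, naming the offender.
    """
    if len(counts) < 10:
        raise ValueError(f"need >= 10 days of data, got {len(counts)}")
    y = counts[group].to_numpy(float)
    t = np.arange(len(counts), dtype=float)
    vr = counts[baseline].to_numpy(float)
    if np.all(y == y[0]):
        raise ValueError(f"response '{group}' is constant")
    if np.all(vr == vr[0]) and not include_intercept:
        # a constant baseline with no intercept is still a valid regressor,
        # but a zero one is degenerate
        if vr[0] == 0:
            raise ValueError(f"baseline regressor '{baseline}' is all zero")
    names = ["beta_t", "beta_baseline"]
    x = np.column_stack([t, vr])
    if include_intercept:
        x = sm.add_constant(x, prepend=False)
        names = names + ["intercept"]
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            f"collinear regressors among (t, {baseline}"
            + (", intercept)" if include_intercept else ")")
        )
    res = sm.OLS(y, x).fit()
    ci = res.conf_int(alpha=0.05)
    se = dict(zip(names, (float(v) for v in res.bse)))
    pv = dict(zip(names, (float(v) for v in res.pvalues)))
    cis = {n: (float(ci[i][0]), float(ci[i][1])) for i, n in enumerate(names)}
    return TrendFit(
        group=group,
        beta_t=float(res.params[0]),
        beta_baseline=float(res.params[1]),
        intercept=float(res.params[2]) if include_intercept else None,
        se=se,
        pvalues=pv,
        conf_int=cis,
        n_days=len(counts),
    )


def weekly_share_curve(
    counts: pd.DataFrame, window_weeks: int = 7
) -> dict[str, VolumeSeries]:
    """Aggregate daily counts to ISO weeks and smooth each group with a
    trailing ``window_weeks`` moving average (partial-prefix rule)."""
    if window_weeks < 1:
        raise ValueError("window_weeks must be >= 1")
    out: dict[str, VolumeSeries] = {}
    if counts.empty:
        return out
    weeks = [_week_start(d) for d in counts.index]
    grouped = counts.groupby(pd.Index(weeks, name="week")).sum()
    for col in counts.columns:
        vals = grouped[col].to_numpy()
        sm_vals = trailing_mean(vals, window_weeks)
        out[col] = VolumeSeries(
            str(col),
            tuple(grouped.index),
            tuple(int(v) for v in vals),
            tuple(float(v) for v in sm_vals),
        )
    return out
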