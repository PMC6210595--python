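"""Between-practice variation statistics.

The headline statistic is the systematic component of variation (SCV), the
McPherson-style estimator of the non-random part of between-unit variation
in a utilisation rate.  For practices i with observed focal counts O_i and
expected counts E_i (the practice's class volume scaled by the pooled share
across practices), on the conventional x100 scale::

    SCV = (100 / k) * sum_i [ ((O_i - E_i) / E_i)^2 - 1 / E_i ]

The second term removes the Poisson sampling contribution; negative raw
values (sampling noise exceeding the Poisson expectation) are truncated at
zero with the raw value retained.  Values are banded low / moderate / high /
very high at 3, 5.4 and 10.  Each month the practice set is trimmed to those
whose share lies within the 5th-95th percentiles of that month's share
distribution (inclusive, linear-interpolation quantiles).

Also here: the exact mid-rank Wilcoxon rank-sum comparison of monthly SCVs
before vs after a communication, standardized prescribing ratios (practice
share over pooled share), and the rolling six-month share ratio relative to
a reference month.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from prescvar.panel_io import parse_period

SCV_BANDS = ((3.0, "low"), (5.4, "moderate"), (10.0, "high"))


class ScvUndefinedError(ValueError):
    """SCV cannot be computed (no expected counts, e.g. pooled share zero)."""


def scv_band(value: float) -> str:
    for bound, label in SCV_BANDS:
        if value < bound:
            return label
    return "very high"


def scv_month(share_panel: pd.DataFrame, month, trim=(5, 95)) -> dict:
    """SCV for one month over the percentile-trimmed practice set.

    Returns the truncated SCV, the raw (possibly negative) value, the
    number of practices used ``k``, the trim bounds on the share scale,
    the number of zero-denominator practices dropped, and the band label.
    Pass ``trim=None`` to use all practices with a defined share.
    """
    m = parse_period(month)
    sub = share_panel[(share_panel["period"] == m) & share_panel["share_defined"]]
    if len(sub) < 2:
        raise ScvUndefinedError(f"fewer than 2 practices with defined share in {m}")

    shares = sub["share_pct"].to_numpy()
    if trim is not None:
        lo, hi = np.percentile(shares, trim)  # linear interpolation (type 7)
        sub = sub[(sub["share_pct"] >= lo) & (sub["share_pct"] <= hi)]
    else:
        lo, hi = float(shares.min()), float(shares.max())

    O = sub["focal_items"].to_numpy(dtype=float)
    cls = sub["class_items"].to_numpy(dtype=float)
    if cls.sum() == 0 or O.sum() == 0:
        raise ScvUndefinedError(f"pooled share is zero in {m}")
    E = cls * (O.sum() / cls.sum())
    dropped = int((E == 0).sum())
    O, E = O[E > 0], E[E > 0]
    k = len(O)
    raw = (100.0 / k) * float(np.sum(((O - E) / E) ** 2 - 1.0 / E))
    value = max(raw, 0.0)
    return {
        "month": str(m),
        "scv": value,
        "scv_raw": raw,
        "k": k,
        "n_dropped_zero_expected": dropped,
        "trim_lo": float(lo),
        "trim_hi": float(hi),
        "band": scv_band(value),
    }


def scv_series(share_panel: pd.DataFrame, months=None, trim=(5, 95)) -> pd.DataFrame:
    """Monthly SCV table over the given months (default: all in panel)."""
    if months is None:
        months = sorted(share_panel["period"].unique())
    return pd.DataFrame([scv_month(share_panel, m, trim=trim) for m in months])


def exact_ranksum_p(x, y, max_exact: int = 12) -> float:
    """Two-sided rank-sum p-value, exact by enumeration with mid-rank ties.

    Enumerates all C(n1+n2, n1) assignments of the pooled mid-ranks to the
    first group and counts splits whose rank sum is at least as far from its
    null mean as the observed one.  Falls back to the normal approximation
    with tie correction when either group exceeds ``max_exact``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if min(n1, n2) == 0:
        raise ValueError("empty group")
    if max(n1, n2) > max_exact:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue)
    ranks = stats.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    d_obs = abs(w_obs - mean_w)
    hits = 0
    for idx in combinations(range(n1 + n2), n1):
        if abs(ranks[list(idx)].sum() - mean_w) >= d_obs - 1e-12:
            hits += 1
    return hits / comb(n1 + n2, n1)


def scv_window_compare(share_panel: pd.DataFrame, dhpc_month, w: int = 6,
                       trim=(5, 95)) -> dict:
    """Compare median monthly SCV in the w months before vs after the
    communication month (the communication month itself in neither window),
    with an exact two-sided Wilcoxon rank-sum p-value."""
    dhpc = parse_period(dhpc_month)
    months = set(share_panel["period"].unique())
    pre = [dhpc - i for i in range(w, 0, -1)]
    post = [dhpc + i for i in range(1, w + 1)]
    if not set(pre) <= months or not set(post) <= months:
        raise ValueError(f"panel lacks {w} months on each side of {dhpc}")
    scv_pre = [scv_month(share_panel, m, trim=trim)["scv"] for m in pre]
    scv_post = [scv_month(share_panel, m, trim=trim)["scv"] for m in post]
    return {
        "median_pre": float(np.median(scv_pre)),
        "median_post": float(np.median(scv_post)),
        "wilcoxon_p": exact_ranksum_p(scv_pre, scv_post),
        "scv_pre": scv_pre,
        "scv_post": scv_post,
    }


def standardized_ratios(share_panel: pd.DataFrame, months=None) -> pd.DataFrame:
    """Per practice-month ratio of the practice share to the pooled share.

    The pooled share for a month is 100 * (sum of focal counts) / (sum of
    class counts) over practices with a defined share; a practice at the
    pooled share has ratio 1.  Undefined shares yield NaN ratios.
    """
    panel = share_panel
    if months is not None:
        months = [parse_period(m) for m in months]
        panel = panel[panel["period"].isin(months)]
    out = []
    for m, sub in panel.groupby("period", sort=True):
        defined = sub[sub["share_defined"]]
        cls = defined["class_items"].sum()
        focal = defined["focal_items"].sum()
        if cls == 0 or focal == 0:
            raise ScvUndefinedError(f"pooled share is zero in {m}")
        pooled = 100.0 * focal / cls
        out.append(
            pd.DataFrame(
                {
                    "practice_id": sub["practice_id"],
                    "period": sub["period"],
                    "ratio": sub["share_pct"] / pooled,
                    "pooled_share": pooled,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


#: Percentile grid: deciles plus the 1st-9th bottom and top percentiles.
RATIO_PERCENTILES = tuple(
    list(range(1, 10)) + list(range(10, 100, 10)) + list(range(91, 100))
)


def ratio_percentiles(ratio_table: pd.DataFrame,
                      percentiles=RATIO_PERCENTILES) -> pd.DataFrame:
    """Per-month percentiles of a ratio table (linear interpolation)."""
    rows = {}
    for m, sub in ratio_table.groupby("period", sort=True):
        vals = sub["ratio"].dropna().to_numpy()
        rows[m] = np.percentile(vals, percentiles) if len(vals) else np.nan
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"p{p}" for p in percentiles]
    )
    out.index.name = "period"
    return out


def rolling_ratio_distribution(share_panel: pd.DataFrame, ref_month,
                               window: int = 6) -> pd.DataFrame:
    """Rolling mean share over the trailing window, relative to a reference
    month.

    For each practice and month m, the mean share over months m-window+1..m
    (requiring all window months defined) is divided by the practice's share
    in ``ref_month``.  Practices with a zero or undefined reference share
    are excluded.  Returns the long ratio table; feed it to
    :func:`ratio_percentiles` for the decile/percentile summary.
    """
    ref = parse_period(ref_month)
    wide = share_panel.pivot(index="period", columns="practice_id",
                             values="share_pct").sort_index()
    if ref not in wide.index:
        raise ValueError(f"reference month {ref} not in panel")
    ref_share = wide.loc[ref]
    keep = ref_share.notna() & (ref_share > 0)
    if not keep.any():
        raise ScvUndefinedError("reference share zero or undefined everywhere")
    rolling = wide.loc[:, keep].rolling(window, min_periods=window).mean()
    ratios = rolling.div(ref_share[keep], axis=1)
    ratios = ratios.iloc[window - 1:]
    long = ratios.reset_index().melt(id_vars="period", var_name="practice_id",
                                     value_name="ratio")
    return long.dropna(subset=["ratio"]).reset_index(drop=True)
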