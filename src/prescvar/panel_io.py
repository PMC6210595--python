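"""Panel construction from NHS-style prescribing extracts.

The practice-prescribing dialect is one row per practice x month x product:
columns ``PRACTICE``, ``PERIOD`` (YYYYMM), ``BNF_CODE``, ``BNF_NAME``
(ignored) and ``ITEMS``.  Products are aggregated into three nested counts
per practice-month using BNF code prefixes: the focal drug (e.g. mirabegron,
``0704020AE``), its therapeutic class (overactive-bladder drugs, BNF section
``070402``) and all items.  The monthly outcome is the focal drug's
percentage share of the class.

A practice-characteristics table (one row per practice: workforce, registered
patient profile, quality indicators, deprivation decile) drives the practice
exclusion rules and the predictor models downstream.

Periods are represented as :class:`pandas.Period` with monthly frequency
throughout, so month arithmetic is ordinary integer arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["practice_id", "period", "focal_items", "class_items", "total_items"]

PROFILE_COLUMNS = [
    "practice_id",
    "list_size",
    "pct_patients_65plus",
    "pct_patients_female",
    "gp_fte",
    "pct_gp_female",
    "pct_gp_45plus",
    "has_registrar",
    "qof_overall_pct",
    "hypertension_prevalence",
    "dementia_prevalence",
    "imd_decile",
]

_PROFILE_PCT_FIELDS = [
    "pct_patients_65plus",
    "pct_patients_female",
    "pct_gp_female",
    "pct_gp_45plus",
    "qof_overall_pct",
]


class PanelError(ValueError):
    """Malformed prescribing input (bad period, codes or counts)."""


def parse_period(value) -> pd.Period:
    """Parse a YYYYMM integer/string (or YYYY-MM) into a monthly Period."""
    s = str(value).strip()
    if s.isdigit() and len(s) == 6:
        year, month = int(s[:4]), int(s[4:])
    else:
        try:
            return pd.Period(s, freq="M")
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise PanelError(f"malformed period {value!r}") from exc
    if not 1 <= month <= 12:
        raise PanelError(f"malformed period {value!r}: month out of range")
    return pd.Period(year=year, month=month, freq="M")


def _as_period_col(col: pd.Series) -> pd.Series:
    return col.map(parse_period)


def read_prescribing(
    path,
    focal_code: str = "0704020AE",
    class_code: str = "070402",
    window: tuple | None = None,
) -> pd.DataFrame:
    """Read a prescribing CSV and aggregate to a practice-month panel.

    Parameters
    ----------
    path
        CSV with columns PRACTICE, PERIOD (YYYYMM), BNF_CODE, ITEMS
        (BNF_NAME, if present, is ignored).
    focal_code, class_code
        BNF code prefixes; ``focal_code`` must extend ``class_code`` so the
        focal counts nest inside the class counts.
    window
        Optional (start, end) months; defaults to the span observed in the
        file.  Practice-months inside the window with no rows are recorded
        as explicit zero-count rows.

    Returns
    -------
    DataFrame with columns practice_id, period, focal_items, class_items,
    total_items — one row per practice per month of the window.
    """
    if not focal_code.startswith(class_code) or focal_code == class_code:
        raise PanelError(
            f"focal code {focal_code!r} must be a strict prefix extension "
            f"of class code {class_code!r}"
        )
    raw = pd.read_csv(path, dtype={"BNF_CODE": str, "PRACTICE": str})
    required = {"PRACTICE", "PERIOD", "BNF_CODE", "ITEMS"}
    missing = required - set(raw.columns)
    if missing:
        raise PanelError(f"prescribing CSV missing columns {sorted(missing)}")
    if len(raw) and (raw["ITEMS"] < 0).any():
        raise PanelError("negative item counts in prescribing CSV")

    if len(raw):
        raw = raw.assign(period=_as_period_col(raw["PERIOD"]))
        code = raw["BNF_CODE"].fillna("")
        raw["focal"] = raw["ITEMS"].where(code.str.startswith(focal_code), 0)
        raw["cls"] = raw["ITEMS"].where(code.str.startswith(class_code), 0)
        agg = (
            raw.groupby(["PRACTICE", "period"], sort=True)
            .agg(
                focal_items=("focal", "sum"),
                class_items=("cls", "sum"),
                total_items=("ITEMS", "sum"),
            )
            .reset_index()
            .rename(columns={"PRACTICE": "practice_id"})
        )
    else:
        agg = pd.DataFrame(columns=PANEL_COLUMNS)

    if window is not None:
        start, end = (parse_period(window[0]), parse_period(window[1]))
    elif len(agg):
        start, end = agg["period"].min(), agg["period"].max()
    else:
        return agg[PANEL_COLUMNS]

    months = pd.period_range(start, end, freq="M")
    agg = agg[(agg["period"] >= start) & (agg["period"] <= end)]
    practices = sorted(agg["practice_id"].unique())
    full = pd.MultiIndex.from_product(
        [practices, months], names=["practice_id", "period"]
    )
    panel = (
        agg.set_index(["practice_id", "period"])
        .reindex(full, fill_value=0)
        .reset_index()
    )
    return validate_panel(panel[PANEL_COLUMNS])


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check the nested-count invariant 0 <= focal <= class <= total."""
    for col in ("focal_items", "class_items", "total_items"):
        if (panel[col] < 0).any():
            raise PanelError(f"negative {col}")
    if (panel["focal_items"] > panel["class_items"]).any():
        raise PanelError("focal_items exceeds class_items")
    if (panel["class_items"] > panel["total_items"]).any():
        raise PanelError("class_items exceeds total_items")
    return panel


def write_prescribing(panel: pd.DataFrame, path,
                      focal_code: str = "0704020AE",
                      class_code: str = "070402") -> None:
    """Write a panel back to the prescribing-CSV dialect.

    Counts are decomposed into three synthetic product rows per
    practice-month (focal drug, rest of class, rest of all items) so that
    :func:`read_prescribing` reproduces the panel exactly.
    """
    rows = []
    other_class = class_code + "ZZ"
    other_total = "9999999999"
    for rec in panel.itertuples(index=False):
        period = f"{rec.period.year:04d}{rec.period.month:02d}"
        rest_class = rec.class_items - rec.focal_items
        rest_total = rec.total_items - rec.class_items
        if rec.focal_items > 0:
            rows.append((rec.practice_id, period, focal_code, "FOCAL DRUG",
                         rec.focal_items))
        if rest_class > 0:
            rows.append((rec.practice_id, period, other_class, "OTHER CLASS",
                         rest_class))
        if rest_total > 0:
            rows.append((rec.practice_id, period, other_total, "OTHER ITEMS",
                         rest_total))
    out = pd.DataFrame(rows, columns=["PRACTICE", "PERIOD", "BNF_CODE",
                                      "BNF_NAME", "ITEMS"])
    out.to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    """Read a practice-characteristics CSV and validate field ranges."""
    prof = pd.read_csv(path, dtype={"practice_id": str})
    missing = set(PROFILE_COLUMNS) - set(prof.columns)
    if missing:
        raise PanelError(f"characteristics CSV missing columns {sorted(missing)}")
    prof["has_registrar"] = prof["has_registrar"].astype(bool)
    return validate_profiles(prof[PROFILE_COLUMNS])


def validate_profiles(prof: pd.DataFrame) -> pd.DataFrame:
    for col in _PROFILE_PCT_FIELDS:
        vals = prof[col].dropna()
        if ((vals < 0) | (vals > 100)).any():
            raise PanelError(f"{col} outside [0, 100]")
    decile = prof["imd_decile"].dropna()
    if (~decile.isin(range(1, 11))).any():
        raise PanelError("imd_decile outside 1..10")
    if (prof["list_size"].dropna() < 0).any():
        raise PanelError("negative list_size")
    if (prof["gp_fte"].dropna() < 0).any():
        raise PanelError("negative gp_fte")
    return prof


def write_profiles(prof: pd.DataFrame, path) -> None:
    prof[PROFILE_COLUMNS].to_csv(path, index=False)


def apply_exclusions(
    panel: pd.DataFrame,
    profiles: pd.DataFrame,
    dhpc_month,
    min_list: int = 750,
    min_per_fte: float = 500,
    max_per_fte: float = 5000,
    min_items: int = 100,
    items_col: str = "total_items",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove atypical and low-volume practices.

    A practice is excluded if its list size is below ``min_list``, if its
    registered patients per FTE GP fall below ``min_per_fte`` or above
    ``max_per_fte`` (strict inequalities; the boundary is retained), if the
    per-FTE ratio is undefined (no GP FTEs with a nonzero list), or if its
    monthly item count drops below ``min_items`` in any month of the
    13 months either side of the safety-communication month (for a September
    2015 communication: August 2014 through October 2016).  ``items_col``
    selects whether the volume rule counts all items (default) or class
    items.

    Returns the filtered panel and a report with one row per excluded
    practice giving the first rule triggered (checked in the order above)
    and the offending value.
    """
    dhpc = parse_period(dhpc_month)
    if not (panel["period"] == dhpc).any():
        raise PanelError(f"DHPC month {dhpc} not present in panel")
    prof = profiles.set_index("practice_id")
    panel_ids = pd.Index(panel["practice_id"].unique())
    unknown = panel_ids.difference(prof.index)
    if len(unknown):
        raise PanelError(f"practices missing from profiles: {list(unknown)[:5]}")

    lo, hi = dhpc - 13, dhpc + 13
    vol_window = panel[(panel["period"] >= lo) & (panel["period"] <= hi)]
    min_monthly = vol_window.groupby("practice_id")[items_col].min()

    records = []
    for pid in panel_ids:
        row = prof.loc[pid]
        rule = value = None
        per_fte = row["list_size"] / row["gp_fte"] if row["gp_fte"] > 0 else np.nan
        if row["list_size"] < min_list:
            rule, value = "min_list", row["list_size"]
        elif row["gp_fte"] == 0 and row["list_size"] > 0:
            rule, value = "per_fte_undefined", np.inf
        elif per_fte < min_per_fte:
            rule, value = "per_fte_low", per_fte
        elif per_fte > max_per_fte:
            rule, value = "per_fte_high", per_fte
        elif pid in min_monthly.index and min_monthly[pid] < min_items:
            rule, value = "low_volume", min_monthly[pid]
        if rule is not None:
            records.append((pid, rule, float(value)))

    report = pd.DataFrame(records, columns=["practice_id", "rule", "value"])
    keep = ~panel["practice_id"].isin(report["practice_id"])
    return panel[keep].reset_index(drop=True), report


def compute_share(panel: pd.DataFrame) -> pd.DataFrame:
    """Add the outcome: the focal drug's percentage share of class items.

    ``share_pct`` is 100 * focal / class where the class denominator is
    positive and NaN (undefined) where it is zero; undefined rows are kept
    in the frame but flagged via ``share_defined`` so downstream stages can
    drop them rather than impute zero.
    """
    out = panel.copy()
    cls = out["class_items"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        share = np.where(cls > 0, 100.0 * out["focal_items"] / cls, np.nan)
    out["share_pct"] = share
    out["share_defined"] = cls > 0
    return out


def summarise_month(share_panel: pd.DataFrame, month) -> dict:
    """Descriptive summary of one month across included practices.

    Returns the percentage of practices prescribing the focal drug at all,
    moments of the share distribution over practices with a defined share,
    and mean class/focal item counts.
    """
    m = parse_period(month)
    sub = share_panel[share_panel["period"] == m]
    if sub.empty:
        raise PanelError(f"month {m} absent from panel")
    n = len(sub)
    shares = sub.loc[sub["share_defined"], "share_pct"]
    q1, q3 = (shares.quantile([0.25, 0.75]) if len(shares) else (np.nan, np.nan))
    return {
        "month": str(m),
        "n_practices": n,
        "pct_practices_prescribing": 100.0 * (sub["focal_items"] > 0).sum() / n,
        "mean_share": float(shares.mean()),
        "sd_share": float(shares.std(ddof=1)),
        "median_share": float(shares.median()),
        "iqr": (float(q1), float(q3)),
        "mean_class_items": float(sub["class_items"].mean()),
        "mean_focal_items": float(sub["focal_items"].mean()),
    }
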