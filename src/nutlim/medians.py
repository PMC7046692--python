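"""Date-window, growing-season and eligibility filters, and median summaries.

Concentration medians are computed per site and analyte over the growing
season only — May–October north of the Tropic of Cancer, November–April
south of the Tropic of Capricorn, year-round within the tropics — from the
most recent seven years of each site's record inside 1990–2016. A site is
eligible when it retains at least 37 samples collected no less often than
roughly every two months (median inter-sample gap <= 61 days). Catchments
holding several eligible sites are pooled as the median of site medians.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from nutlim.tables_io import StageLog

NH_MONTHS = frozenset({5, 6, 7, 8, 9, 10})
SH_MONTHS = frozenset({11, 12, 1, 2, 3, 4})


@dataclasses.dataclass(frozen=True)
class SeasonPolicy:
    nh_months: frozenset[int] = NH_MONTHS
    sh_months: frozenset[int] = SH_MONTHS
    tropics_abs_lat: float = 23.43695

    def __post_init__(self) -> None:
        if self.nh_months | self.sh_months != frozenset(range(1, 13)) or (
            self.nh_months & self.sh_months
        ):
            raise ValueError("hemisphere month sets must partition the year")


@dataclasses.dataclass(frozen=True)
class EligibilityPolicy:
    min_samples: int = 37
    max_interval_days: float = 61.0
    window_years: int = 7
    year_min: int = 1990
    year_max: int = 2016


def filter_window(samples: pd.DataFrame,
                  policy: EligibilityPolicy = EligibilityPolicy(),
                  log: StageLog | None = None) -> pd.DataFrame:
    """Keep, per site–analyte, the most recent ``window_years`` of data within the study years."""
    df = samples.copy()
    in_range = (df["date"].dt.year >= policy.year_min) & (df["date"].dt.year <= policy.year_max)
    df = df.loc[in_range]
    if df.empty:
        if log is not None:
            log.record(len(samples), 0, {"outside_date_range": len(samples)})
        return df.reset_index(drop=True)
    last = df.groupby(["site_id", "analyte"])["date"].transform("max")
    start = last - pd.DateOffset(years=policy.window_years)
    recent = df["date"] >= start
    out = df.loc[recent].reset_index(drop=True)
    if log is not None:
        log.record(len(samples), len(out), {
            "outside_date_range": int((~in_range).sum()),
            "older_than_window": int((~recent).sum()),
        })
    return out


def filter_season(samples: pd.DataFrame, sites: pd.DataFrame,
                  policy: SeasonPolicy = SeasonPolicy(),
                  log: StageLog | None = None) -> pd.DataFrame:
    """Keep growing-season months outside the tropics; all months within them."""
    lat = sites.set_index("site_id")["latitude"]
    missing = set(samples["site_id"]) - set(lat.index)
    if missing:
        raise ValueError(f"sample site(s) missing from site table: {sorted(missing)[:5]}")
    site_lat = samples["site_id"].map(lat)
    month = samples["date"].dt.month
    tropical = site_lat.abs() <= policy.tropics_abs_lat
    nh = site_lat > policy.tropics_abs_lat
    keep = tropical | (nh & month.isin(policy.nh_months)) | (
        ~tropical & ~nh & month.isin(policy.sh_months)
    )
    if log is not None:
        log.record(len(samples), int(keep.sum()), {"off_season": int((~keep).sum())})
    return samples.loc[keep].reset_index(drop=True)


def check_eligibility(dates: pd.Series,
                      policy: EligibilityPolicy = EligibilityPolicy()) -> tuple[bool, list[str]]:
    """Sample-count and sampling-frequency eligibility for one site–analyte series.

    Eligible iff n >= ``min_samples`` and the median gap between consecutive
    sampling dates is at most ``max_interval_days`` ("at least once every two
    months"). Returns (eligible, reasons).
    """
    reasons = []
    n = len(dates)
    if n < policy.min_samples:
        reasons.append("too_few_samples")
    if n >= 2:
        gaps = np.diff(np.sort(pd.to_datetime(dates).to_numpy())).astype("timedelta64[D]")
        if float(np.median(gaps.astype(float))) > policy.max_interval_days:
            reasons.append("too_infrequent")
    return (not reasons), reasons


def site_median(values) -> float:
    """Middle-value median (mean of the two central order statistics for even n)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty series")
    return float(np.median(arr))


def site_medians_table(samples: pd.DataFrame, sites: pd.DataFrame,
                       policy: EligibilityPolicy = EligibilityPolicy(),
                       log: StageLog | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site, per-analyte medians for eligible series.

    Returns ``(medians, exclusions)``; medians follow the ``site_medians``
    schema and exclusions list ineligible site–analyte pairs with reasons.
    """
    catchment = sites.set_index("site_id")["catchment_id"]
    rows, excl = [], []
    for (sid, analyte), grp in samples.groupby(["site_id", "analyte"], sort=True):
        ok, reasons = check_eligibility(grp["date"], policy)
        if not ok:
            excl.append({"site_id": sid, "analyte": analyte, "reason": ";".join(reasons)})
            continue
        rows.append({
            "site_id": sid,
            "catchment_id": catchment.get(sid, ""),
            "analyte": analyte,
            "median_mgL": site_median(grp["value"]),
            "n_samples": len(grp),
            "window_start": grp["date"].min(),
            "window_end": grp["date"].max(),
        })
    cols = ["site_id", "catchment_id", "analyte", "median_mgL", "n_samples",
            "window_start", "window_end"]
    med = pd.DataFrame(rows, columns=cols)
    exclusions = pd.DataFrame(excl, columns=["site_id", "analyte", "reason"])
    if log is not None:
        n_series = med.shape[0] + exclusions.shape[0]
        reasons = exclusions["reason"].value_counts().to_dict() if len(exclusions) else {}
        log.record(n_series, med.shape[0], reasons)
    return med, exclusions


def catchment_median(site_medians: pd.DataFrame) -> pd.DataFrame:
    """Pool site medians to one observed median per catchment and analyte."""
    if site_medians.empty:
        return pd.DataFrame(columns=["catchment_id", "analyte", "median_mgL", "n_sites"])
    out = (
        site_medians.groupby(["catchment_id", "analyte"], sort=True)["median_mgL"]
        .agg(median_mgL="median", n_sites="size")
        .reset_index()
    )
    return out
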