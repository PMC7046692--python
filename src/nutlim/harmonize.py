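"""Harmonisation of raw nutrient sample records.

Three screens, applied per site–analyte series:

1. unit-anomaly screening — values two orders of magnitude above the series
   median are flagged as likely unit mix-ups (µg vs mg) and excluded, never
   silently corrected;
2. left-censoring handling — censored values are substituted at half the
   detection limit, but a series with more than 10% censored points is
   excluded outright;
3. analytical-method acceptance — TN/TP must come from strong-acid or
   acidified-persulfate digestion of unfiltered samples, DRP from samples
   filtered below 0.7 µm, and nitrate from one of four comparable methods.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from nutlim.tables_io import StageLog, logger

#: default accepted analytical-method codes
DEFAULT_TN_TP_METHODS = frozenset({
    "strong_acid_digestion", "persulfate_digestion", "acid_persulfate_digestion",
})
DEFAULT_NO3_METHODS = frozenset({
    "ion_chromatography", "cadmium_reduction", "azo_dye_colorimetry", "optical_sensor",
})


@dataclasses.dataclass(frozen=True)
class CensoringPolicy:
    """Half-detection-limit substitution with the 10% exclusion rule."""

    substitution_fraction: float = 0.5
    max_censored_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.substitution_fraction < 1:
            raise ValueError("substitution_fraction must be in (0, 1)")
        if not 0 < self.max_censored_fraction < 1:
            raise ValueError("max_censored_fraction must be in (0, 1)")


@dataclasses.dataclass(frozen=True)
class MethodPolicy:
    """Accepted analytical methods per analyte family."""

    accepted_tn_tp_methods: frozenset[str] = DEFAULT_TN_TP_METHODS
    drp_max_pore_um: float = 0.7
    accepted_no3_methods: frozenset[str] = DEFAULT_NO3_METHODS

    def __post_init__(self) -> None:
        if not self.accepted_tn_tp_methods or not self.accepted_no3_methods:
            raise ValueError("accepted method sets must be non-empty")


def screen_anomalies(samples: pd.DataFrame, factor: float = 100.0,
                     log: StageLog | None = None) -> pd.DataFrame:
    """Flag probable unit mix-ups within each site–analyte series.

    A value at least ``factor`` times the series median (default 100x, i.e.
    a µg-recorded-as-mg error and then some) gains ``flag = "suspect_units"``
    and is dropped from the returned frame. Single-sample series have no
    reference median and are never flagged.
    """
    if samples.empty:
        raise ValueError("screen_anomalies requires at least one sample")
    df = samples.copy()
    grp = df.groupby(["site_id", "analyte"])["value"]
    med = grp.transform("median")
    n = grp.transform("size")
    suspect = (n > 1) & (med > 0) & (df["value"] >= factor * med)
    n_flag = int(suspect.sum())
    if n_flag:
        logger.info("screen_anomalies: flagged %d suspect-unit value(s)", n_flag)
    if log is not None:
        log.record(len(df), len(df) - n_flag, {"suspect_units": n_flag})
    return df.loc[~suspect].reset_index(drop=True)


def impute_censored(samples: pd.DataFrame,
                    policy: CensoringPolicy = CensoringPolicy(),
                    log: StageLog | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Substitute censored values at half the detection limit, or exclude the site.

    Returns ``(retained, exclusions)``. Within each site–analyte series: if
    the censored fraction exceeds ``max_censored_fraction`` (strictly; exactly
    10% is retained) the whole series is excluded with reason
    ``too_censored``; otherwise each censored value is replaced by
    ``substitution_fraction`` x its detection limit. Uncensored values are
    never altered.
    """
    df = samples.copy()
    bad_dl = df["censored"] & df["detection_limit"].isna()
    if bad_dl.any():
        raise ValueError(
            f"{int(bad_dl.sum())} censored sample(s) lack a detection limit"
        )
    frac = df.groupby(["site_id", "analyte"])["censored"].transform("mean")
    excluded_mask = frac > policy.max_censored_fraction
    retained = df.loc[~excluded_mask].copy()
    sub = retained["censored"]
    retained.loc[sub, "value"] = (
        policy.substitution_fraction * retained.loc[sub, "detection_limit"]
    )
    excl = (
        df.loc[excluded_mask, ["site_id", "analyte"]]
        .drop_duplicates()
        .assign(reason="too_censored")
        .reset_index(drop=True)
    )
    if log is not None:
        log.record(len(df), len(retained), {"too_censored": int(excluded_mask.sum())})
    return retained.reset_index(drop=True), excl


def screen_methods(samples: pd.DataFrame,
                   policy: MethodPolicy = MethodPolicy(),
                   log: StageLog | None = None) -> pd.DataFrame:
    """Retain only samples measured with accepted analytical methods.

    Rejections are tallied per reason (never raised): ``unknown_method`` for
    TN/TP/NO3N codes outside the accepted sets, ``pore_too_coarse`` for DRP
    filtered at >= 0.7 µm or with no pore size recorded.
    """
    df = samples.copy()
    analyte = df["analyte"]
    code = df["method_code"].astype(str)
    keep = pd.Series(False, index=df.index)
    reasons: dict[str, int] = {}

    is_tn_tp = analyte.isin(["TN", "TP"])
    keep |= is_tn_tp & code.isin(policy.accepted_tn_tp_methods)
    is_no3 = analyte == "NO3N"
    keep |= is_no3 & code.isin(policy.accepted_no3_methods)
    is_drp = analyte == "DRP"
    pore_ok = df["filter_pore_um"].notna() & (df["filter_pore_um"] < policy.drp_max_pore_um)
    keep |= is_drp & pore_ok

    n_unknown = int(((is_tn_tp | is_no3) & ~keep).sum())
    n_pore = int((is_drp & ~pore_ok).sum())
    if n_unknown:
        reasons["unknown_method"] = n_unknown
        rejected_codes = code[(is_tn_tp | is_no3) & ~keep].value_counts()
        logger.info("screen_methods: rejected codes %s", rejected_codes.to_dict())
    if n_pore:
        reasons["pore_too_coarse"] = n_pore
    if log is not None:
        log.record(len(df), int(keep.sum()), reasons)
    return df.loc[keep].reset_index(drop=True)


def harmonize_all(samples: pd.DataFrame,
                  censoring: CensoringPolicy = CensoringPolicy(),
                  methods: MethodPolicy = MethodPolicy(),
                  unit_anomaly_factor: float = 100.0,
                  log: StageLog | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the three harmonisation screens in order; returns (samples, exclusions)."""
    out = screen_anomalies(samples, factor=unit_anomaly_factor, log=log)
    out = screen_methods(out, policy=methods, log=log)
    out, excl = impute_censored(out, policy=censoring, log=log)
    return out, excl
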