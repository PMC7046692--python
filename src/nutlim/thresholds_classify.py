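"""Literature nutrient-threshold summaries and the four-way catchment classifier.

Each catchment with predicted TN and TP medians is placed in one of four
types by crossing the limiting nutrient with the enrichment status of that
nutrient. The mass N:P ratio of 7 (the Redfield ratio expressed by mass)
splits N-limitation (< 7) from P-limitation (>= 7); the limiting nutrient's
concentration is then compared with the literature mean threshold for
undesirable periphyton growth (defaults: TN 0.800 mg/L, TP 0.046 mg/L):

    type 1 - N-limited, acceptable growth     (ratio < 7, TN <= threshold)
    type 2 - N-limited, undesirable growth    (ratio < 7, TN  > threshold)
    type 3 - P-limited, acceptable growth     (ratio >= 7, TP <= threshold)
    type 4 - P-limited, undesirable growth    (ratio >= 7, TP  > threshold)

A concentration exactly at its threshold is classed acceptable by default
(the source rules use strict inequalities on both sides, leaving equality
undefined; acceptable is the conservative reading and is configurable).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

TYPE_CODE = {("N", "acceptable"): 1, ("N", "undesirable"): 2,
             ("P", "acceptable"): 3, ("P", "undesirable"): 4}


@dataclasses.dataclass(frozen=True)
class ClassificationRule:
    """Ratio boundary (mass N:P) and the two total-nutrient thresholds (mg/L)."""

    ratio_boundary: float = 7.0
    tn_threshold: float = 0.800
    tp_threshold: float = 0.046
    equality_is_undesirable: bool = False

    def __post_init__(self) -> None:
        if min(self.ratio_boundary, self.tn_threshold, self.tp_threshold) <= 0:
            raise ValueError("rule parameters must be positive")


@dataclasses.dataclass(frozen=True)
class ThresholdSummary:
    analyte: str
    mean: float
    se: float
    min: float
    max: float
    n_studies: int


def summarize_thresholds(studies: pd.DataFrame, analyte: str) -> ThresholdSummary:
    """Arithmetic mean, standard error (sd/sqrt(n)), and range of survey thresholds."""
    vals = studies.loc[studies["analyte"] == analyte, "threshold_mgL"].to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(f"need >= 2 studies for {analyte} (SE undefined otherwise)")
    return ThresholdSummary(
        analyte=analyte,
        mean=float(vals.mean()),
        se=float(vals.std(ddof=1) / np.sqrt(vals.size)),
        min=float(vals.min()),
        max=float(vals.max()),
        n_studies=int(vals.size),
    )


def anova_thresholds_by_biome(studies: pd.DataFrame, analyte: str | None = None) -> dict:
    """One-way ANOVA of survey thresholds across biomes.

    Returns F, p, group means, and the between/within sum-of-squares
    decomposition. Requires at least two biomes with at least two studies each.
    """
    df = studies if analyte is None else studies.loc[studies["analyte"] == analyte]
    groups = {b: g["threshold_mgL"].to_numpy(dtype=float)
              for b, g in df.groupby("biome")}
    usable = {b: v for b, v in groups.items() if v.size >= 2}
    if len(usable) < 2:
        raise ValueError("ANOVA needs >= 2 biomes with >= 2 studies each")
    arrays = list(usable.values())
    F, p = stats.f_oneway(*arrays)
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in arrays)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in arrays)
    return {
        "F": float(F),
        "p": float(p),
        "group_means": {b: float(v.mean()) for b, v in usable.items()},
        "ss_between": float(ss_between),
        "ss_within": float(ss_within),
        "df_between": len(usable) - 1,
        "df_within": int(allv.size - len(usable)),
    }


def classify_catchment(tn_median: float, tp_median: float,
                       rule: ClassificationRule = ClassificationRule()) -> dict:
    """Classify one catchment from its TN and TP medians (mg/L).

    Returns a dict with ``np_ratio``, ``limitation`` ('N' or 'P'), ``growth``
    ('acceptable' or 'undesirable') and ``type_code`` (1-4). The four rules
    partition the positive quadrant exactly.
    """
    if tn_median <= 0 or tp_median <= 0:
        raise ValueError("TN and TP medians must be positive")
    ratio = tn_median / tp_median
    # quotients like 0.70/0.100 sit one ulp off the boundary; treat a ratio
    # within relative 1e-9 of it as exactly at the boundary (P-limited branch)
    at_boundary = abs(ratio - rule.ratio_boundary) <= 1e-9 * rule.ratio_boundary
    if ratio < rule.ratio_boundary and not at_boundary:
        limitation, conc, thr = "N", tn_median, rule.tn_threshold
    else:
        limitation, conc, thr = "P", tp_median, rule.tp_threshold
    if rule.equality_is_undesirable:
        undesirable = conc >= thr
    else:
        undesirable = conc > thr
    growth = "undesirable" if undesirable else "acceptable"
    return {
        "tn_median": tn_median,
        "tp_median": tp_median,
        "np_ratio": ratio,
        "limitation": limitation,
        "growth": growth,
        "type_code": TYPE_CODE[(limitation, growth)],
    }


def classify_table(predictions: pd.DataFrame,
                   rule: ClassificationRule = ClassificationRule()) -> pd.DataFrame:
    """Classify a table with columns ``catchment_id, tn_median, tp_median``."""
    rows = []
    for _, r in predictions.iterrows():
        out = classify_catchment(float(r["tn_median"]), float(r["tp_median"]), rule)
        out["catchment_id"] = r["catchment_id"]
        rows.append(out)
    cols = ["catchment_id", "tn_median", "tp_median", "np_ratio",
            "limitation", "growth", "type_code"]
    return pd.DataFrame(rows, columns=cols)


def classify_with_regional_thresholds(predictions: pd.DataFrame,
                                      regions: pd.DataFrame,
                                      catchment_region: pd.Series | dict,
                                      areas: pd.Series | dict,
                                      fallback: ClassificationRule = ClassificationRule(),
                                      missing_region: str = "fallback") -> dict:
    """Classify under region-specific thresholds and under the global rule set.

    ``regions`` has columns ``region, tn_threshold, tp_threshold`` (both
    thresholds required — a region with only one raises); ``catchment_region``
    maps catchment_id to region (missing mapping handled per
    ``missing_region``: 'fallback' applies the global rule, 'exclude' drops
    the catchment); ``areas`` maps catchment_id to km². Returns both
    classification tables plus a per-region area-by-type difference report.
    """
    if missing_region not in ("fallback", "exclude"):
        raise ValueError("missing_region must be 'fallback' or 'exclude'")
    reg = regions.set_index("region")
    partial = reg["tn_threshold"].isna() ^ reg["tp_threshold"].isna()
    if partial.any():
        raise ValueError(
            f"region(s) with partial thresholds: {list(reg.index[partial])}")
    reg = reg.dropna(subset=["tn_threshold", "tp_threshold"])
    cr = pd.Series(catchment_region)
    ar = pd.Series(areas, dtype=float)

    global_types = classify_table(predictions, fallback)
    rows = []
    for _, r in predictions.iterrows():
        cid = r["catchment_id"]
        region = cr.get(cid)
        if region is None or region not in reg.index:
            if missing_region == "exclude":
                continue
            rule, region = fallback, region or "(none)"
        else:
            rule = ClassificationRule(
                ratio_boundary=fallback.ratio_boundary,
                tn_threshold=float(reg.loc[region, "tn_threshold"]),
                tp_threshold=float(reg.loc[region, "tp_threshold"]),
                equality_is_undesirable=fallback.equality_is_undesirable,
            )
        out = classify_catchment(float(r["tn_median"]), float(r["tp_median"]), rule)
        out["catchment_id"] = cid
        out["region"] = region
        rows.append(out)
    regional_types = pd.DataFrame(rows)

    # area in each type under both rule sets, per region and in total
    merged = regional_types.merge(
        global_types[["catchment_id", "type_code"]].rename(
            columns={"type_code": "type_global"}),
        on="catchment_id")
    merged["area_km2"] = merged["catchment_id"].map(ar)
    diff_rows = []
    scopes = [("all", merged)] + [(rg, g) for rg, g in merged.groupby("region")]
    for scope, g in scopes:
        total = g["area_km2"].sum()
        for t in (1, 2, 3, 4):
            a_reg = g.loc[g["type_code"] == t, "area_km2"].sum()
            a_glo = g.loc[g["type_global"] == t, "area_km2"].sum()
            diff_rows.append({
                "region": scope, "type_code": t,
                "area_regional_km2": a_reg, "area_global_km2": a_glo,
                "percent_difference": (100.0 * (a_reg - a_glo) / total) if total else 0.0,
            })
    return {
        "regional": regional_types,
        "global": global_types,
        "difference": pd.DataFrame(diff_rows),
    }
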