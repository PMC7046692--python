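"""Continent- and world-level roll-ups of classified catchments.

Sums area, population and land use over (grouping, catchment type) cells,
always on unrounded values; rounding to the reporting precision (0.1 M km²)
happens only when a table is rendered. The world row sums the continents,
optionally excluding named regions (by default Antarctica and Greenland,
which carry no classified river catchments in the source framing).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from nutlim.tables_io import LANDUSE_COLUMNS

TYPES = (1, 2, 3, 4)


def _merged(results: pd.DataFrame, catchments: pd.DataFrame) -> pd.DataFrame:
    need = ["catchment_id", "continent", "area_km2", "population", *LANDUSE_COLUMNS]
    m = results.merge(catchments[need], on="catchment_id", how="left", validate="one_to_one")
    if m["continent"].isna().any():
        missing = m.loc[m["continent"].isna(), "catchment_id"].tolist()
        raise ValueError(f"catchment(s) missing from catchment table or lacking a continent: {missing[:5]}")
    return m


def aggregate(results: pd.DataFrame, catchments: pd.DataFrame,
              group_by: str = "continent",
              excluded_regions: tuple[str, ...] = ("Antarctica", "Greenland")) -> pd.DataFrame:
    """Area/population/land-use totals per (group, type), plus a world row.

    ``results`` must carry ``catchment_id`` and ``type_code``; attributes come
    from the catchment table. ``area_percent`` is each type's share of its
    group's classified area, computed from unrounded sums. With
    ``group_by='world'`` only the world row is returned.
    """
    m = _merged(results, catchments)
    m = m.loc[~m["continent"].isin(excluded_regions)]
    if m.empty:
        raise ValueError("no classified catchments to aggregate")

    def roll(df: pd.DataFrame, label: str) -> list[dict]:
        total_area = df["area_km2"].sum()
        rows = []
        for t in TYPES:
            g = df.loc[df["type_code"] == t]
            row = {
                "group": label, "type_code": t,
                "area_km2": float(g["area_km2"].sum()),
                "area_percent": float(100.0 * g["area_km2"].sum() / total_area),
                "population": int(g["population"].sum()),
            }
            for c in LANDUSE_COLUMNS:
                row[c] = float(g[c].sum())
            rows.append(row)
        return rows

    rows: list[dict] = []
    if group_by == "continent":
        for cont, g in m.groupby("continent", sort=True):
            rows.extend(roll(g, cont))
    elif group_by != "world":
        raise ValueError("group_by must be 'continent' or 'world'")
    rows.extend(roll(m, "World"))
    return pd.DataFrame(rows)


def headline_percentages(table: pd.DataFrame) -> dict:
    """Headline shares from an aggregate table's world row.

    ``pct_undesirable`` is the share of classified area in types 2 and 4
    (undesirable periphyton growth); the N/P shares split that undesirable
    area by limiting nutrient; populations are reported per type.
    """
    world = table.loc[table["group"] == "World"].set_index("type_code")
    if world.empty:
        raise ValueError("aggregate table has no World row")
    area = world["area_km2"]
    total = float(area.sum())
    if total <= 0:
        raise ValueError("zero total classified area")
    und = float(area.get(2, 0.0) + area.get(4, 0.0))
    return {
        "pct_undesirable": 100.0 * und / total,
        "pct_N_of_undesirable": (100.0 * float(area.get(2, 0.0)) / und) if und else 0.0,
        "pct_P_of_undesirable": (100.0 * float(area.get(4, 0.0)) / und) if und else 0.0,
        "populations_by_type": {int(t): int(world.loc[t, "population"])
                                for t in TYPES if t in world.index},
    }


def landuse_breakdown(results: pd.DataFrame, catchments: pd.DataFrame,
                      excluded_regions: tuple[str, ...] = ("Antarctica", "Greenland")
                      ) -> pd.DataFrame:
    """Agriculture/forest/other areas and within-cell percentages per (continent, type)."""
    m = _merged(results, catchments)
    over = m[list(LANDUSE_COLUMNS)].sum(axis=1) > m["area_km2"] * (1 + 1e-6)
    if over.any():
        raise ValueError(
            f"land-use areas exceed catchment area for: "
            f"{m.loc[over, 'catchment_id'].tolist()[:5]}")
    m = m.loc[~m["continent"].isin(excluded_regions)]
    rows = []
    scopes = list(m.groupby("continent", sort=True)) + [("World", m)]
    for cont, g in scopes:
        for t in TYPES:
            cell = g.loc[g["type_code"] == t]
            sums = {c: float(cell[c].sum()) for c in LANDUSE_COLUMNS}
            cell_total = sum(sums.values())
            row = {"group": cont, "type_code": t, **sums}
            for c in LANDUSE_COLUMNS:
                row[c.replace("_km2", "_percent")] = (
                    100.0 * sums[c] / cell_total if cell_total else 0.0)
            rows.append(row)
    return pd.DataFrame(rows)


def render_area_table(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Report view: areas in millions of km² (rounded) with percent in parentheses."""
    out = table.copy()
    out["area_Mkm2"] = (out["area_km2"] / 1e6).round(decimals)
    out["cell"] = out.apply(
        lambda r: f"{r['area_Mkm2']:.{decimals}f} ({r['area_percent']:.0f})", axis=1)
    return out.pivot(index="group", columns="type_code", values="cell")
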