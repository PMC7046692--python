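"""Baseflow separation and baseflow-day sample filtering.

Daily discharge is split into slow (baseflow) and storm-driven (quickflow)
components with the Lyne–Hollick recursive digital filter. Nutrient samples
are then restricted to days dominated by baseflow (default: baseflow at
least 75% of that day's flow), on the grounds that storm flows scour
periphyton and carry sediment that confounds concentration medians. Sample
sites are paired with a discharge gauge no more than 50 km downstream.

Filter form, per pass over flow Q::

    qf_t = alpha * qf_{t-1} + ((1 + alpha) / 2) * (Q_t - Q_{t-1})

with quickflow clamped to [0, Q_t]; baseflow = Q - qf becomes the input to
the next pass, and passes alternate forward/backward. The series is padded by
reflection at both ends to warm the recursion up, and gaps in the flow
record split it into independently filtered segments.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from nutlim.tables_io import StageLog, logger


@dataclasses.dataclass
class BaseflowResult:
    """Baseflow/quickflow split of one gauge's daily series.

    ``bfi`` is the baseflow index: mean baseflow over mean flow, in [0, 1].
    Days in segments too short to filter hold NaN.
    """

    gauge_id: str
    dates: pd.DatetimeIndex
    flow: np.ndarray
    baseflow: np.ndarray
    quickflow: np.ndarray
    alpha: float
    passes: int
    bfi: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gauge_id": self.gauge_id,
            "date": self.dates,
            "flow_m3s": self.flow,
            "baseflow_m3s": self.baseflow,
            "quickflow_m3s": self.quickflow,
        })


def _single_pass(q: np.ndarray, alpha: float) -> np.ndarray:
    """One forward Lyne–Hollick pass; returns baseflow. Sequential by nature."""
    n = q.size
    qf = 0.0
    b = np.empty(n)
    b[0] = q[0]
    for t in range(1, n):
        qf = alpha * qf + 0.5 * (1.0 + alpha) * (q[t] - q[t - 1])
        qf = min(max(qf, 0.0), q[t])
        b[t] = q[t] - qf
    return b


def _filter_segment(q: np.ndarray, alpha: float, passes: int, reflect: int) -> np.ndarray:
    pad = min(reflect, q.size - 1)
    x = np.concatenate([q[pad:0:-1], q, q[-2:-2 - pad:-1]]) if pad else q.copy()
    for p in range(passes):
        if p % 2 == 1:
            x = _single_pass(x[::-1], alpha)[::-1]
        else:
            x = _single_pass(x, alpha)
    return x[pad:pad + q.size] if pad else x


def lyne_hollick_filter(discharge: pd.DataFrame, alpha: float = 0.925,
                        passes: int = 3, reflect_days: int = 30,
                        min_segment_days: int = 10) -> BaseflowResult:
    """Separate one gauge's daily discharge into baseflow and quickflow.

    Parameters
    ----------
    discharge
        Frame with columns ``gauge_id, date, flow_m3s`` for a single gauge,
        on a strictly daily grid; missing days may appear as NaN flow or as
        absent rows (they are reinserted as NaN and break the series into
        segments, each filtered independently if at least
        ``min_segment_days`` long).
    alpha
        Filter recession constant in (0, 1); 0.925 is the conventional
        daily-data value.
    passes
        Odd number of alternating forward/backward passes (default 3).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if passes < 1 or passes % 2 == 0:
        raise ValueError("passes must be odd and >= 1")
    gauges = discharge["gauge_id"].unique()
    if len(gauges) != 1:
        raise ValueError(f"expected a single gauge, got {list(gauges)}")
    df = discharge.sort_values("date")
    dates = pd.DatetimeIndex(df["date"])
    if dates.has_duplicates:
        raise ValueError("duplicate dates in discharge series")
    # reindex onto the full daily grid; absent days become NaN
    full = pd.date_range(dates[0], dates[-1], freq="D")
    flow = df.set_index("date")["flow_m3s"].reindex(full).to_numpy(dtype=float)
    if np.all(np.isnan(flow)):
        raise ValueError("discharge series has no non-missing flow")
    if (flow[~np.isnan(flow)] < 0).any():
        raise ValueError("negative flow")

    baseflow = np.full(flow.size, np.nan)
    for start, stop in _segments(flow):
        if stop - start >= min_segment_days:
            baseflow[start:stop] = _filter_segment(flow[start:stop], alpha, passes, reflect_days)
    quickflow = flow - baseflow
    valid = ~np.isnan(baseflow)
    if not valid.any():
        raise ValueError(
            f"no segment of >= {min_segment_days} consecutive days to filter"
        )
    mean_flow = float(np.mean(flow[valid]))
    bfi = float(np.mean(baseflow[valid]) / mean_flow) if mean_flow > 0 else 1.0
    return BaseflowResult(
        gauge_id=str(gauges[0]), dates=full, flow=flow, baseflow=baseflow,
        quickflow=quickflow, alpha=alpha, passes=passes, bfi=bfi,
    )


def _segments(flow: np.ndarray):
    """Yield (start, stop) index pairs of maximal non-missing runs."""
    isnum = ~np.isnan(flow)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], isnum.view(np.int8), [0]])))
    for i in range(0, edges.size, 2):
        yield int(edges[i]), int(edges[i + 1])


def baseflow_fraction_on(result: BaseflowResult, date) -> float:
    """Baseflow share of the day's flow; 1.0 on zero-flow days (no quickflow possible)."""
    date = pd.Timestamp(date).normalize()
    if date < result.dates[0] or date > result.dates[-1]:
        raise ValueError(f"{date.date()} outside the gauged span")
    i = int((date - result.dates[0]).days)
    q = result.flow[i]
    if np.isnan(q) or np.isnan(result.baseflow[i]):
        raise ValueError(f"no filtered flow record on {date.date()}")
    if q == 0:
        return 1.0
    return float(result.baseflow[i] / q)


def link_site_to_gauge(site_id: str, links: pd.DataFrame,
                       max_km: float = 50.0) -> str | None:
    """Return the gauge linked to a site within ``max_km`` downstream (inclusive).

    With several qualifying gauges the nearest wins. Returns None when no
    gauge qualifies; such sites drop out of the baseflow filter and the
    analysis.
    """
    cand = links.loc[links["site_id"] == site_id]
    if (cand["downstream_km"] < 0).any():
        raise ValueError(f"negative downstream distance for site {site_id}")
    cand = cand.loc[cand["downstream_km"] <= max_km]
    if cand.empty:
        logger.info("site %s: no gauge within %.0f km", site_id, max_km)
        return None
    return str(cand.sort_values("downstream_km").iloc[0]["gauge_id"])


def filter_baseflow_samples(samples: pd.DataFrame, links: pd.DataFrame,
                            baseflow_results: dict[str, BaseflowResult],
                            min_fraction: float = 0.75, max_km: float = 50.0,
                            log: StageLog | None = None) -> pd.DataFrame:
    """Retain samples taken on days with baseflow fraction >= ``min_fraction``.

    Exclusion reasons tallied in ``log``: ``no_gauge`` (site unlinked within
    ``max_km``), ``no_flow_record`` (sample date missing from the filtered
    discharge record), ``stormflow`` (fraction below the minimum).
    """
    reasons = {"no_gauge": 0, "no_flow_record": 0, "stormflow": 0}
    keep = np.zeros(len(samples), dtype=bool)
    gauge_of: dict[str, str | None] = {}
    for pos, (_, row) in enumerate(samples.iterrows()):
        sid = row["site_id"]
        if sid not in gauge_of:
            gauge_of[sid] = link_site_to_gauge(sid, links, max_km=max_km)
        gid = gauge_of[sid]
        if gid is None or gid not in baseflow_results:
            reasons["no_gauge"] += 1
            continue
        try:
            frac = baseflow_fraction_on(baseflow_results[gid], row["date"])
        except ValueError:
            reasons["no_flow_record"] += 1
            continue
        if frac >= min_fraction:
            keep[pos] = True
        else:
            reasons["stormflow"] += 1
    if log is not None:
        log.record(len(samples), int(keep.sum()), {k: v for k, v in reasons.items() if v})
    return samples.loc[keep].reset_index(drop=True)
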