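"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations (explicit loops,
brute-force enumeration) kept separate from the package's implementations so
that agreement between the two routes is meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nutlim import synthetic_data as sd


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_lyne_hollick(flow, alpha=0.925, passes=3, reflect=30):
    """Hand-iterated recursive filter: reflect-pad, alternate directions,
    clamp quickflow to [0, Q], baseflow of each pass feeds the next."""
    q = list(map(float, flow))
    pad = min(reflect, len(q) - 1)
    series = list(reversed(q[1:pad + 1])) + q + list(reversed(q[-pad - 1:-1]))
    for p in range(passes):
        if p % 2 == 1:
            series = list(reversed(series))
        out = [series[0]]
        qf = 0.0
        for t in range(1, len(series)):
            qf = alpha * qf + 0.5 * (1 + alpha) * (series[t] - series[t - 1])
            qf = min(max(qf, 0.0), series[t])
            out.append(series[t] - qf)
        series = list(reversed(out)) if p % 2 == 1 else out
    return np.array(series[pad:pad + len(q)])


def oracle_best_subset_by_cp(X, y):
    """Brute-force Cp minimisation with per-subset least squares via lstsq."""
    import itertools
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, k = X.shape

    def sse_of(cols):
        D = np.column_stack([np.ones(n)] + [X[:, j] for j in cols])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        r = y - D @ beta
        return float(r @ r)

    sse_full = sse_of(tuple(range(k)))
    sigma2 = sse_full / (n - (k + 1))
    best, best_key = None, None
    for r in range(k + 1):
        for cols in itertools.combinations(range(k), r):
            cp = sse_of(cols) / sigma2 - n + 2 * (1 + len(cols))
            key = (cp, 1 + len(cols), cols)
            if best_key is None or key < best_key:
                best, best_key = cols, key
    return best, best_key[0]


def oracle_median(values):
    """Sort-based middle-value median."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mid = n // 2
    return v[mid] if n % 2 else 0.5 * (v[mid - 1] + v[mid])


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_world():
    return sd.generate_world(preset="small", seed=7)


@pytest.fixture()
def sample_frame():
    """Minimal valid sample table: one tropical site, uncensored TN."""
    dates = pd.date_range("2010-01-10", periods=40, freq="14D")
    return pd.DataFrame({
        "site_id": "S1",
        "date": dates,
        "analyte": "TN",
        "value": np.linspace(0.4, 0.9, len(dates)),
        "detection_limit": 0.01,
        "censored": False,
        "method_code": "persulfate_digestion",
        "filter_pore_um": np.nan,
    })


@pytest.fixture()
def table1_fixture():
    """Catchment/type tables encoding the continental area roll-up worked example.

    One catchment per (continent, type) cell; areas in km² chosen so that the
    continent-level cells are 22.7/6.1/0.0/1.1 M km² (Africa), etc. Zero-area
    cells are simply absent.
    """
    cells = {
        "Africa": (22.7, 6.1, 0.0, 1.1),
        "Asia": (19.4, 4.2, 8.1, 12.5),
        "Europe": (2.2, 0.0, 0.6, 6.6),
        "North America": (11.7, 0.0, 4.2, 6.1),
        "Oceania": (3.8, 0.8, 0.3, 2.6),
        "South America": (15.6, 0.0, 0.7, 1.5),
    }
    catch_rows, type_rows = [], []
    for cont, areas in cells.items():
        for t, a in enumerate(areas, start=1):
            if a == 0.0:
                continue
            cid = f"{cont[:2]}{t}"
            catch_rows.append({
                "catchment_id": cid, "continent": cont, "area_km2": a * 1e6,
                "population": 1000, "landuse_agriculture_km2": a * 4e5,
                "landuse_forest_km2": a * 4e5, "landuse_other_km2": a * 2e5,
            })
            type_rows.append({"catchment_id": cid, "type_code": t})
    return pd.DataFrame(type_rows), pd.DataFrame(catch_rows)
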