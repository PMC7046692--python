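"""Synthetic worlds with known truth for exercising the full pipeline.

Everything the pipeline ingests can be generated here: daily hydrographs
(slow baseflow recession plus Poisson storm pulses with a two-day decay
half-life), site networks spanning both hemispheres and the tropics,
left-censored log-normal concentration series, catchment predictor tables
driven by a sparse linear model in log space, and a literature-style
threshold survey. Each generator is a pure function of its parameters and
seed, and the :class:`SyntheticTruth` record keeps every quantity needed to
score recovery downstream (true coefficients, true log-medians, true
baseflow shares, detection limits).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from nutlim.tables_io import write_table

CONTINENTS = ("Africa", "Asia", "Europe", "North America", "Oceania", "South America")
BIOMES = ("temperate_forest", "grassland", "desert_xeric", "tropical_forest", "tundra")

#: default log-space intercepts, i.e. geometric-mean medians of roughly
#: 0.6, 0.04, 0.30 and 0.010 mg/L for TN, TP, NO3-N and DRP
DEFAULT_INTERCEPTS = {"TN": -0.51, "TP": -3.22, "NO3N": -1.20, "DRP": -4.60}

#: quickflow decay per day for a two-day half-life
_STORM_DECAY = 0.5 ** 0.5


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a generated world."""

    seed: int
    active_predictors: tuple[str, ...]
    beta_true: dict[str, dict[str, float]]      # analyte -> predictor -> coef
    intercepts: dict[str, float]                # analyte -> log-space intercept
    sigma_true: float                           # catchment-level residual sd (log)
    catchment_ids: tuple[str, ...]
    true_log_median: dict[str, np.ndarray]      # analyte -> per-catchment values
    bfi_true: dict[str, float] = dataclasses.field(default_factory=dict)
    censor_dl: dict[str, float] = dataclasses.field(default_factory=dict)

    def true_median_frame(self, analytes=("TN", "TP")) -> pd.DataFrame:
        """Catchment table of true (noise-free) medians, mg/L."""
        out = pd.DataFrame({"catchment_id": self.catchment_ids})
        for a in analytes:
            out[f"{a.lower()}_median"] = np.exp(self.true_log_median[a])
        return out

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["true_log_median"] = {k: v.tolist() for k, v in self.true_log_median.items()}
        Path(path).write_text(json.dumps(payload, indent=2))


def gen_discharge(n_days: int = 1826, base_level: float = 5.0,
                  recession_rate: float = 0.05, storm_rate: float = 0.08,
                  storm_size: float = 10.0, seed: int = 0,
                  gauge_id: str = "G1",
                  start: str = "2010-01-01") -> tuple[pd.DataFrame, float]:
    """Daily hydrograph: recessing baseflow store plus storm pulses.

    Storms arrive as Bernoulli(storm_rate) events; each pulse (exponential
    magnitude, mean ``storm_size * base_level``) feeds quickflow (90%),
    which decays with a two-day half-life, and recharges the baseflow store
    (10%), which relaxes back toward ``base_level`` at ``recession_rate``
    per day. Returns the discharge table and the generated baseflow share
    ``bfi_true``.
    """
    if min(n_days, base_level, recession_rate, storm_size) <= 0 or not 0 <= storm_rate <= 1:
        raise ValueError("parameters must be positive (storm_rate a probability)")
    rng = np.random.default_rng(seed)
    events = rng.random(n_days) < storm_rate
    pulse = np.where(events, rng.exponential(storm_size * base_level, n_days), 0.0)
    b = np.empty(n_days)
    q = np.empty(n_days)
    b[0], q[0] = base_level, 0.9 * pulse[0]
    for t in range(1, n_days):
        b[t] = b[t - 1] + recession_rate * (base_level - b[t - 1]) + 0.1 * pulse[t]
        q[t] = _STORM_DECAY * q[t - 1] + 0.9 * pulse[t]
    flow = b + q
    bfi_true = float(b.sum() / flow.sum())
    df = pd.DataFrame({
        "gauge_id": gauge_id,
        "date": pd.date_range(start, periods=n_days, freq="D"),
        "flow_m3s": flow,
    })
    return df, bfi_true


def gen_catchment_table(n_catchments: int = 60, n_predictors: int = 8,
                        n_active: int = 2, beta_scale: float = 1.0,
                        sigma: float = 0.3, seed: int = 0,
                        analytes: tuple[str, ...] = ("TN", "TP"),
                        intercepts: dict[str, float] | None = None,
                        ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Catchment predictors and the sparse log-space truth behind the medians.

    Continuous predictors are standard normal; one categorical biome column
    has five levels (inactive in the truth). The first ``n_active``
    continuous predictors carry coefficients of alternating sign and
    magnitude ``beta_scale``. Areas are log-uniform over 100-100,000 km²,
    population tracks the first predictor, and land use is a Dirichlet split
    of each catchment's area.
    """
    if n_active > n_predictors:
        raise ValueError("n_active cannot exceed n_predictors")
    rng = np.random.default_rng(seed)
    intercepts = dict(intercepts or DEFAULT_INTERCEPTS)
    ids = tuple(f"C{i:04d}" for i in range(n_catchments))
    X = rng.standard_normal((n_catchments, n_predictors))
    pred_names = [f"x_{j + 1}" for j in range(n_predictors)]
    active = tuple(pred_names[:n_active])
    signs = np.array([1.0 if j % 2 == 0 else -1.0 for j in range(n_active)])

    beta_true: dict[str, dict[str, float]] = {}
    true_log: dict[str, np.ndarray] = {}
    for a in analytes:
        beta = {nm: float(beta_scale * signs[j]) for j, nm in enumerate(active)}
        beta_true[a] = beta
        true_log[a] = intercepts[a] + X[:, :n_active] @ (beta_scale * signs)

    area = 10.0 ** rng.uniform(2, 5, n_catchments)
    population = np.round(np.exp(10.0 + 0.8 * X[:, 0] + rng.normal(0, 0.5, n_catchments)))
    landuse = rng.dirichlet(np.array([2.0, 2.0, 1.0]), n_catchments) * area[:, None]

    df = pd.DataFrame({
        "catchment_id": ids,
        "continent": [CONTINENTS[i % len(CONTINENTS)] for i in range(n_catchments)],
        "area_km2": area,
        "population": population.astype(int),
        "landuse_agriculture_km2": landuse[:, 0],
        "landuse_forest_km2": landuse[:, 1],
        "landuse_other_km2": landuse[:, 2],
    })
    for j, nm in enumerate(pred_names):
        df[nm] = X[:, j]
    df["c_biome"] = rng.choice(BIOMES, n_catchments)

    truth = SyntheticTruth(
        seed=seed, active_predictors=active, beta_true=beta_true,
        intercepts=intercepts, sigma_true=sigma, catchment_ids=ids,
        true_log_median=true_log,
    )
    return df, truth


def gen_observed_medians(truth: SyntheticTruth, seed: int = 0,
                         analytes: tuple[str, ...] = ("TN", "TP")) -> pd.DataFrame:
    """Catchment medians observed with log-normal residual noise sd ``sigma_true``."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in analytes:
        obs = np.exp(truth.true_log_median[a]
                     + rng.normal(0, truth.sigma_true, len(truth.catchment_ids)))
        for cid, v in zip(truth.catchment_ids, obs):
            rows.append({"catchment_id": cid, "analyte": a,
                         "median_mgL": float(v), "n_sites": 1})
    return pd.DataFrame(rows)


def gen_sites_and_samples(truth: SyntheticTruth, n_sites: int | None = None,
                          lat_range: tuple[float, float] = (-45.0, 60.0),
                          schedule_days: int = 14, n_years: int = 5,
                          censor_target: float = 0.05, sigma_sample: float = 0.5,
                          seed: int = 0, analytes: tuple[str, ...] = ("TN", "TP"),
                          start: str = "2010-01-15",
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Site network, sampling records and site-gauge links for a truth table.

    One site per catchment by default (site i monitors catchment i), each
    linked to its own gauge 1-40 km downstream. Site latitudes spread across
    ``lat_range`` so both hemispheres and the tropics are populated. Sample
    concentrations are log-normal around the site's true log-median (offset
    by a catchment-residual draw of sd ``sigma_true``); each site-analyte
    series gets a detection limit at the ``censor_target`` quantile of its
    own distribution, so the realised censored fraction concentrates there.
    Censored rows carry the detection limit in ``value``.
    """
    if not 0 <= censor_target <= 0.3:
        raise ValueError("censor_target must be in [0, 0.3]")
    rng = np.random.default_rng(seed)
    n_catch = len(truth.catchment_ids)
    n_sites = n_catch if n_sites is None else n_sites
    site_ids = [f"S{i:04d}" for i in range(n_sites)]
    lats = rng.uniform(lat_range[0], lat_range[1], n_sites)
    sites = pd.DataFrame({
        "site_id": site_ids,
        "latitude": lats,
        "catchment_id": [truth.catchment_ids[i % n_catch] for i in range(n_sites)],
    })
    links = pd.DataFrame({
        "site_id": site_ids,
        "gauge_id": [f"G{i:04d}" for i in range(n_sites)],
        "downstream_km": rng.uniform(1.0, 40.0, n_sites),
    })

    dates = pd.date_range(start, periods=int(n_years * 365.25 / schedule_days),
                          freq=f"{schedule_days}D")
    method = {"TN": "persulfate_digestion", "TP": "persulfate_digestion",
              "NO3N": "cadmium_reduction", "DRP": "molybdenum_blue"}
    rows = []
    for i, sid in enumerate(site_ids):
        ci = i % n_catch
        for a in analytes:
            mu = truth.true_log_median[a][ci] + rng.normal(0, truth.sigma_true)
            vals = np.exp(mu + rng.normal(0, sigma_sample, len(dates)))
            if censor_target > 0:
                dl = float(np.exp(mu + sigma_sample * stats.norm.ppf(censor_target)))
            else:
                dl = float(np.exp(mu - 8 * sigma_sample))
            cens = vals < dl
            vals = np.where(cens, dl, vals)
            pore = 0.45 if a == "DRP" else np.nan
            for d, v, c in zip(dates, vals, cens):
                rows.append({
                    "site_id": sid, "date": d, "analyte": a, "value": float(v),
                    "detection_limit": dl, "censored": bool(c),
                    "method_code": method[a], "filter_pore_um": pore,
                })
            truth.censor_dl[a] = dl
    samples = pd.DataFrame(rows)
    return sites, samples, links


def gen_threshold_survey(n_studies: int = 27,
                         analyte_means: dict[str, float] | None = None,
                         biomes: tuple[str, ...] = BIOMES[:4], seed: int = 0,
                         cv: float = 0.5) -> pd.DataFrame:
    """Literature-style threshold survey, log-normal around each analyte mean.

    Analytes are assigned round-robin across the studies; the log-normal is
    parameterised so its arithmetic mean equals the requested analyte mean
    (coefficient of variation ``cv``). Biome means are equal by construction,
    so a downstream ANOVA across biomes should reject at about the nominal
    rate only.
    """
    analyte_means = dict(analyte_means or {"TN": 0.800, "TP": 0.046})
    if min(analyte_means.values()) <= 0:
        raise ValueError("analyte means must be positive")
    rng = np.random.default_rng(seed)
    s = float(np.sqrt(np.log1p(cv ** 2)))
    analytes = list(analyte_means)
    rows = []
    for i in range(n_studies):
        a = analytes[i % len(analytes)]
        mean = analyte_means[a]
        thr = float(np.exp(np.log(mean) - s ** 2 / 2 + s * rng.standard_normal())) if cv > 0 else mean
        rows.append({
            "study_id": f"study_{i + 1:02d}",
            "analyte": a,
            "threshold_mgL": thr,
            "biome": biomes[i % len(biomes)],
            "region": ("US", "China", "Europe", "South America", "Africa",
                       "Australasia")[i % 6],
        })
    return pd.DataFrame(rows)


PRESETS = {
    "small": dict(n_catchments=60, n_predictors=8, n_active=2, n_years=5),
    "medium": dict(n_catchments=200, n_predictors=10, n_active=3, n_years=6),
}


def generate_world(preset: str = "small", seed: int = 42,
                   censor_target: float = 0.05, sigma: float = 0.3,
                   analytes: tuple[str, ...] = ("TN", "TP")) -> dict:
    """Generate every pipeline input at a named scale; fully seed-determined."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    cfg = PRESETS[preset]
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)]

    catchments, truth = gen_catchment_table(
        n_catchments=cfg["n_catchments"], n_predictors=cfg["n_predictors"],
        n_active=cfg["n_active"], sigma=sigma, seed=seeds[0], analytes=analytes)
    sites, samples, links = gen_sites_and_samples(
        truth, n_years=cfg["n_years"], censor_target=censor_target,
        seed=seeds[1], analytes=analytes)
    n_days = int(cfg["n_years"] * 365.25) + 60
    discharge_parts = []
    gauge_rng = np.random.default_rng(seeds[2])
    for gid in links["gauge_id"]:
        d, bfi = gen_discharge(
            n_days=n_days, seed=int(gauge_rng.integers(2 ** 31)), gauge_id=gid,
            start="2010-01-01")
        truth.bfi_true[gid] = bfi
        discharge_parts.append(d)
    discharge = pd.concat(discharge_parts, ignore_index=True)
    thresholds = gen_threshold_survey(seed=seeds[3])
    return {
        "catchments": catchments, "sites": sites, "samples": samples,
        "links": links, "discharge": discharge, "thresholds": thresholds,
        "truth": truth,
    }


def write_world(world: dict, outdir: str | Path) -> None:
    """Write a generated world's tables as the pipeline's CSV inputs + truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(world["samples"], outdir / "samples.csv", "samples")
    write_table(world["sites"], outdir / "sites.csv", "sites")
    write_table(world["links"], outdir / "site_gauge_links.csv", "site_gauge_links")
    write_table(world["discharge"], outdir / "discharge.csv", "discharge")
    write_table(world["catchments"], outdir / "catchments.csv", "catchments")
    write_table(world["thresholds"], outdir / "thresholds.csv", "thresholds")
    world["truth"].to_json(outdir / "truth.json")
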