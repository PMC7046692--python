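"""Log-space best-subsets regression with smearing retransformation.

Catchment median concentrations are strongly right-skewed, so models are fit
to the natural log of the median. Subset selection is exhaustive over
predictor blocks (a categorical predictor's indicator columns enter and
leave together), scored with the Mallows Cp statistic

    Cp = SSE_p / sigma2_full - n + 2 p,

where ``sigma2_full`` is the residual variance of the model with every
candidate predictor and ``p`` counts coefficients including the intercept.
The full model satisfies Cp = p identically, and an unbiased subset has
Cp close to p; the default rule takes the Cp-minimising subset.

Back-transforming a log-space prediction by exponentiation alone is biased
low; predictions are multiplied by Duan's smearing factor

    S = (1/n) * sum_i exp(eps_hat_i)  >=  1,

the mean of the exponentiated residuals, applied uniformly under the
homoscedasticity assumption.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from nutlim.tables_io import logger


# ---------------------------------------------------------------------------
# Design-matrix expansion
# ---------------------------------------------------------------------------

def expand_design(X: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand categoricals to indicators grouped in blocks.

    Continuous columns pass through as one-column blocks. Each categorical
    (object/category dtype) column becomes indicator columns with the most
    frequent level dropped as reference; the indicators form a single block
    selected together.
    """
    cols, blocks = [], {}
    for name in X.columns:
        col = X[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.astype(float))
            blocks[name] = [name]
        else:
            counts = col.astype(str).value_counts()
            ref = counts.index[0]
            levels = [lv for lv in sorted(counts.index) if lv != ref]
            members = []
            for lv in levels:
                ind_name = f"{name}[{lv}]"
                cols.append((col.astype(str) == lv).astype(float).rename(ind_name))
                members.append(ind_name)
            blocks[name] = members
    Z = pd.concat(cols, axis=1) if cols else pd.DataFrame(index=X.index)
    return Z, blocks


def _check_full_rank(Z: np.ndarray, names: list[str]) -> None:
    n, k = Z.shape
    if n <= k:
        raise ValueError(f"design has {n} rows for {k} columns; need n > p")
    rank = np.linalg.matrix_rank(Z)
    if rank < k:
        # R's diagonal identifies which columns the rank breaks on
        _, rm = np.linalg.qr(Z)
        diag = np.abs(np.diag(rm))
        tol = diag.max() * max(Z.shape) * np.finfo(float).eps
        bad = [names[j] for j in range(k) if diag[j] < tol] or names
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


# ---------------------------------------------------------------------------
# Cp and subset search
# ---------------------------------------------------------------------------

def mallows_cp(sse_p: float, p: int, sigma2_full: float, n: int) -> float:
    """Mallows Cp = SSE_p / sigma2_full - n + 2p (p counts the intercept)."""
    if sigma2_full <= 0:
        raise ValueError("sigma2_full must be positive")
    return sse_p / sigma2_full - n + 2 * p


@dataclasses.dataclass
class SubsetSearchResult:
    """All evaluated subsets with SSE, parameter count and Cp, plus the choice."""

    candidates: pd.DataFrame  # columns: subset (tuple of block names), sse, p, cp
    chosen: tuple[str, ...]
    sigma2_full: float
    blocks: dict[str, list[str]]
    screened_pool: tuple[str, ...]  # candidate blocks after any pre-screen


def _subset_sse_factory(Z: np.ndarray, y: np.ndarray):
    """Closure computing SSE for a column-index subset from precomputed Gram pieces."""
    X1 = np.column_stack([np.ones(len(y)), Z])
    G = X1.T @ X1
    c = X1.T @ y
    yty = float(y @ y)

    def sse(col_idx: tuple[int, ...]) -> float:
        idx = np.concatenate([[0], np.asarray(col_idx, dtype=int) + 1]).astype(int)
        sol = np.linalg.solve(G[np.ix_(idx, idx)], c[idx])
        return max(yty - float(c[idx] @ sol), 0.0)

    return sse


def best_subsets(X: pd.DataFrame, y, max_exhaustive: int = 20,
                 selection_rule: str = "min_cp") -> SubsetSearchResult:
    """Search predictor-block subsets for the Cp-optimal model.

    All subsets are enumerated when the number of blocks is at most
    ``max_exhaustive``; beyond that a forward-stepwise pre-screen (greedy SSE
    reduction) caps the pool first. Ties are broken toward fewer parameters,
    then lexicographic block names. ``selection_rule='cp_le_p'`` instead picks
    the smallest model with Cp <= p.
    """
    y = np.asarray(y, dtype=float)
    Z_df, blocks = expand_design(X)
    Z = Z_df.to_numpy(dtype=float)
    names = list(Z_df.columns)
    _check_full_rank(np.column_stack([np.ones(len(y)), Z]), ["(intercept)"] + names)
    block_names = list(blocks.keys())
    col_of = {nm: i for i, nm in enumerate(names)}
    sse_of = _subset_sse_factory(Z, y)

    n = len(y)
    p_full = 1 + Z.shape[1]
    sse_full = sse_of(tuple(range(Z.shape[1])))
    if n <= p_full + 1:
        raise ValueError("need n > p_full + 1 for the full-model variance estimate")
    sigma2_full = sse_full / (n - p_full)
    if sigma2_full <= 0:
        raise ValueError("full model is saturated; sigma2_full is zero")

    pool = block_names
    if len(block_names) > max_exhaustive:
        pool = _forward_screen(block_names, blocks, col_of, sse_of, max_exhaustive)

    records = []
    for r in range(len(pool) + 1):
        for combo in itertools.combinations(sorted(pool), r):
            cols = tuple(col_of[m] for b in combo for m in blocks[b])
            sse = sse_of(cols)
            p = 1 + len(cols)
            records.append((combo, sse, p, mallows_cp(sse, p, sigma2_full, n)))
    cand = pd.DataFrame(records, columns=["subset", "sse", "p", "cp"])

    if selection_rule == "min_cp":
        chosen = min(records, key=lambda r: (r[3], r[2], r[0]))[0]
    elif selection_rule == "cp_le_p":
        ok = [r for r in records if r[3] <= r[2]]
        chosen = min(ok or records, key=lambda r: (r[2], r[3], r[0]))[0]
    else:
        raise ValueError(f"unknown selection_rule {selection_rule!r}")
    return SubsetSearchResult(cand, tuple(chosen), float(sigma2_full), blocks, tuple(pool))


def _forward_screen(block_names, blocks, col_of, sse_of, cap: int) -> list[str]:
    """Greedy forward selection by SSE to cap the exhaustive-search pool."""
    selected: list[str] = []
    remaining = set(block_names)
    current_cols: tuple[int, ...] = ()
    while remaining and len(selected) < cap:
        best_name, best_sse = None, np.inf
        for nm in sorted(remaining):
            cols = current_cols + tuple(col_of[m] for m in blocks[nm])
            s = sse_of(cols)
            if s < best_sse:
                best_name, best_sse = nm, s
        selected.append(best_name)
        remaining.discard(best_name)
        current_cols = current_cols + tuple(col_of[m] for m in blocks[best_name])
    return selected


# ---------------------------------------------------------------------------
# OLS fit, smearing, prediction
# ---------------------------------------------------------------------------

def smearing_factor(residuals) -> float:
    """Duan smearing factor: mean of exponentiated residuals (>= 1 when they sum to 0)."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("no residuals")
    return float(np.mean(np.exp(r)))


@dataclasses.dataclass
class RegressionModel:
    """A fitted log-space model for one analyte.

    ``beta`` is keyed by expanded-design column names; ``selected_predictors``
    by original block names. ``smearing`` is S from the training residuals.
    """

    analyte: str
    selected_predictors: tuple[str, ...]
    blocks: dict[str, list[str]]
    beta: dict[str, float]
    intercept: float
    residuals: np.ndarray
    sigma2_hat: float
    r2: float
    smearing: float
    n: int
    p: int
    coef_se: dict[str, float]
    coef_p: dict[str, float]

    def design_row(self, predictors: pd.DataFrame) -> np.ndarray:
        """Linear predictor X.beta (no intercept) for catchment rows."""
        missing = [b for b in self.selected_predictors if b not in predictors.columns]
        if missing:
            raise KeyError(f"missing predictor(s): {missing}")
        Z, _ = expand_design(predictors[list(self.selected_predictors)])
        lin = np.zeros(len(predictors))
        for name, b in self.beta.items():
            if name in Z.columns:
                lin = lin + b * Z[name].to_numpy(dtype=float)
            # indicator absent => that level does not occur in these rows
        return lin

    def to_json(self, path: str | Path) -> None:
        payload = {
            "analyte": self.analyte,
            "selected_predictors": list(self.selected_predictors),
            "blocks": {k: list(v) for k, v in self.blocks.items()},
            "beta": self.beta,
            "intercept": self.intercept,
            "sigma2_hat": self.sigma2_hat,
            "r2": self.r2,
            "smearing": self.smearing,
            "n": self.n,
            "p": self.p,
            "coef_se": self.coef_se,
            "coef_p": self.coef_p,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RegressionModel":
        d = json.loads(Path(path).read_text())
        return cls(
            analyte=d["analyte"],
            selected_predictors=tuple(d["selected_predictors"]),
            blocks={k: list(v) for k, v in d["blocks"].items()},
            beta=d["beta"], intercept=d["intercept"],
            residuals=np.array([]), sigma2_hat=d["sigma2_hat"], r2=d["r2"],
            smearing=d["smearing"], n=d["n"], p=d["p"],
            coef_se=d["coef_se"], coef_p=d["coef_p"],
        )


def fit_ols(X: pd.DataFrame, y_log, subset: tuple[str, ...] | None = None,
            analyte: str = "") -> RegressionModel:
    """Ordinary least squares on the chosen predictor blocks, in log space.

    ``y_log`` is ln(median mg/L). Reports per-coefficient t-test p-values
    (significance at P < 0.05 is reported, never used for selection).
    """
    y_log = np.asarray(y_log, dtype=float)
    if subset is None:
        subset = tuple(X.columns)
    Z_df, blocks = expand_design(X[list(subset)]) if subset else (
        pd.DataFrame(index=X.index), {})
    exog = sm.add_constant(Z_df.to_numpy(dtype=float) if len(Z_df.columns)
                           else np.empty((len(y_log), 0)), has_constant="add")
    _check_full_rank(exog, ["(intercept)"] + list(Z_df.columns))
    res = sm.OLS(y_log, exog).fit()
    resid = np.asarray(res.resid)
    names = list(Z_df.columns)
    beta = {nm: float(res.params[i + 1]) for i, nm in enumerate(names)}
    dof = res.df_resid
    return RegressionModel(
        analyte=analyte,
        selected_predictors=tuple(subset),
        blocks={b: blocks[b] for b in subset},
        beta=beta,
        intercept=float(res.params[0]),
        residuals=resid,
        sigma2_hat=float(resid @ resid / dof) if dof > 0 else 0.0,
        r2=float(res.rsquared) if exog.shape[1] > 1 else 0.0,
        smearing=smearing_factor(resid),
        n=int(res.nobs),
        p=exog.shape[1],
        coef_se={nm: float(res.bse[i + 1]) for i, nm in enumerate(names)},
        coef_p={nm: float(res.pvalues[i + 1]) for i, nm in enumerate(names)},
    )


def predict_concentration(model: RegressionModel, predictors: pd.DataFrame) -> np.ndarray:
    """Back-transformed, smearing-corrected predicted medians (mg/L, > 0)."""
    lin = model.design_row(predictors)
    return np.exp(model.intercept + lin) * model.smearing


def log_transform_check(medians) -> dict:
    """Natural-log response plus Shapiro-Wilk normality of raw and logged values."""
    arr = np.asarray(medians, dtype=float)
    bad = np.flatnonzero(arr <= 0)
    if bad.size:
        raise ValueError(f"non-positive median(s) at position(s) {bad[:5].tolist()}")
    log_resp = np.log(arr)
    report = {"response": log_resp, "n": arr.size}
    if arr.size >= 3 and np.ptp(arr) > 0:
        w_raw, p_raw = stats.shapiro(arr)
        w_log, p_log = stats.shapiro(log_resp)
        report.update(w_raw=float(w_raw), p_raw=float(p_raw),
                      w_log=float(w_log), p_log=float(p_log))
        if p_log < 0.05:
            logger.warning("log-transformed response still non-normal (Shapiro p=%.3g)", p_log)
    else:
        report.update(w_raw=np.nan, p_raw=np.nan, w_log=np.nan, p_log=np.nan)
        logger.warning("normality undefined for degenerate response")
    return report


def validate_holdout(model: RegressionModel, predictors: pd.DataFrame,
                     observed_mgL) -> dict:
    """Hold-out validation: r2 (log space), observed-on-predicted slope, percent bias.

    ``r2`` is the squared correlation between ln(observed) and ln(predicted),
    so validating on the training set itself reproduces the training R².
    ``bias_percent`` is 100 * (mean predicted - mean observed) / mean observed
    on the concentration scale.
    """
    obs = np.asarray(observed_mgL, dtype=float)
    if obs.size < 3:
        raise ValueError("holdout needs at least 3 catchments")
    pred = predict_concentration(model, predictors)
    lr = stats.linregress(np.log(pred), np.log(obs))
    return {
        "r2": float(lr.rvalue ** 2),
        "slope": float(lr.slope),
        "bias_percent": float(100.0 * (pred.mean() - obs.mean()) / obs.mean()),
        "n": int(obs.size),
    }


# ---------------------------------------------------------------------------
# Estimator front-end
# ---------------------------------------------------------------------------

class BestSubsetsSmearingRegressor(BaseEstimator, RegressorMixin):
    """Best-subsets log-linear regression with smearing back-transformation.

    Accepts a DataFrame ``X`` of catchment predictors (numeric columns are
    continuous, object/category columns are categorical blocks) and a
    strictly positive response ``y`` (median concentration, mg/L). The model
    is fit to ln(y); ``predict`` returns concentrations corrected for
    retransformation bias by the smearing factor.

    Parameters
    ----------
    max_exhaustive : int, default 20
        Largest predictor-block pool searched exhaustively; larger pools are
        first capped by a forward-stepwise pre-screen.
    selection_rule : {'min_cp', 'cp_le_p'}, default 'min_cp'
        Subset choice: minimise Cp, or smallest model with Cp <= p.

    Attributes
    ----------
    selected_predictors_ : tuple of selected block names
    coef_ : ndarray of coefficients on the expanded selected design
    intercept_ : float, log-space intercept
    smearing_factor_ : float, Duan S (>= 1)
    r2_ : float, training R² in log space
    residuals_ : ndarray of training residuals (log space)
    cp_table_ : DataFrame of every evaluated subset with SSE, p and Cp
    model_ : the underlying :class:`RegressionModel`
    """

    def __init__(self, max_exhaustive: int = 20, selection_rule: str = "min_cp"):
        self.max_exhaustive = max_exhaustive
        self.selection_rule = selection_rule

    def fit(self, X: pd.DataFrame, y, analyte: str = ""):
        X = self._check_X(X)
        y = np.asarray(y, dtype=float)
        if y.ndim != 1 or len(y) != len(X):
            raise ValueError("y must be 1-D and match X")
        if np.any(y <= 0) or np.any(~np.isfinite(y)):
            raise ValueError("response must be strictly positive and finite")
        search = best_subsets(X, np.log(y), max_exhaustive=self.max_exhaustive,
                              selection_rule=self.selection_rule)
        model = fit_ols(X, np.log(y), subset=search.chosen, analyte=analyte)
        self.model_ = model
        self.search_ = search
        self.cp_table_ = search.candidates
        self.selected_predictors_ = model.selected_predictors
        self.coef_ = np.array(list(model.beta.values()))
        self.intercept_ = model.intercept
        self.smearing_factor_ = model.smearing
        self.r2_ = model.r2
        self.residuals_ = model.residuals
        self.n_features_in_ = X.shape[1]
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        return predict_concentration(self.model_, self._check_X(X))

    def _check_X(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        num = X.select_dtypes(include=[np.number])
        if not np.isfinite(num.to_numpy(dtype=float)).all():
            raise ValueError("predictors contain NaN or inf")
        return X

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
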