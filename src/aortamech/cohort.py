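"""Cohort-level statistics for the stiffness/hardening indices.

Quadrant-averaged SSI and dSSI from each case are pooled (quadrants
treated as independent observations, a documented simplification that
ignores within-patient correlation) and analysed with:

* Pearson correlation of the indices with the clinical diameter criterion;
* five-number quadrant summaries (1.5*IQR whisker convention);
* univariate/multivariate logistic regression by Newton-Raphson maximum
  likelihood, with step halving and explicit complete-separation
  detection;
* ROC/AUC by the rank (Mann-Whitney) formulation with half-credit ties
  and the Youden-J optimal probability threshold.

Because the indices span orders of magnitude, logistic covariates enter
as log10(index) by default (switchable to the raw scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ("case_id", "group", "diameter_mm", "quadrant",
                    "SSI", "dSSI")
GROUPS = ("healthy", "aneurysm")
SIGNIFICANCE = 0.05
COEF_CAP = 50.0


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    bad = set(table["group"].unique()) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels: {bad}")
    if (table[["SSI", "dSSI"]] <= 0).any().any():
        raise ValueError("indices must be positive")
    return table


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value (t transform,
    n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson r undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

@dataclass
class LogisticModel:
    """Logistic model p(x) = 1 / (1 + exp(-(b0 + sum_i b_i x_i)))."""

    coefficients: np.ndarray          # [b0, b1, ...]
    covariates: List[str]
    converged: bool
    separated: bool
    log_likelihood: float
    p_values: np.ndarray
    log_scale: bool
    auc: float = np.nan
    optimal_threshold: float = np.nan
    ll_history: List[float] = field(default_factory=list)

    def design(self, table: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.covariates:
            v = table[name].to_numpy(dtype=float)
            cols.append(np.log10(v) if self.log_scale else v)
        x = np.column_stack(cols) if cols else np.empty((len(table), 0))
        return np.column_stack([np.ones(len(table)), x])

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        t = self.design(table) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-t))


def _newton_logistic(X: np.ndarray, y: np.ndarray,
                     tol: float = 1e-8, max_iter: int = 100
                     ) -> Tuple[np.ndarray, bool, List[float]]:
    """Newton-Raphson MLE with step halving; returns (beta, converged,
    log-likelihood history).  The log-likelihood is non-decreasing across
    accepted iterations by construction."""
    n, k = X.shape
    beta = np.zeros(k)

    def loglik(b: np.ndarray) -> float:
        t = X @ b
        return float(y @ t - np.logaddexp(0.0, t).sum())

    ll = loglik(beta)
    history = [ll]
    converged = False
    for _ in range(max_iter):
        t = X @ beta
        p = 1.0 / (1.0 + np.exp(-t))
        g = X.T @ (y - p)
        if np.linalg.norm(g) < tol:
            converged = True
            break
        w = np.maximum(p * (1.0 - p), 1e-12)
        hess = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, g, rcond=None)[0]
        alpha = 1.0
        for _ in range(40):
            ll_new = loglik(beta + alpha * step)
            if ll_new >= ll:
                break
            alpha *= 0.5
        beta = beta + alpha * step
        ll = ll_new
        history.append(ll)
    return beta, converged, history


def fit_logistic(table: pd.DataFrame, covariates: Sequence[str],
                 log_scale: bool = True, tol: float = 1e-8,
                 max_iter: int = 100) -> LogisticModel:
    """Maximum-likelihood logistic fit of group (aneurysm = 1) on the
    requested index covariates.

    Complete separation is detected (coefficients diverging past a cap)
    and reported: coefficients are capped and the model flagged as
    separated with converged=False.
    """
    table = validate_cohort(table) if set(REQUIRED_COLUMNS) <= set(table.columns) \
        else table
    y = (table["group"].to_numpy() == "aneurysm").astype(float) \
        if "group" in table.columns else table["label"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    cols = []
    for name in covariates:
        v = table[name].to_numpy(dtype=float)
        cols.append(np.log10(v) if log_scale else v)
    X = np.column_stack([np.ones(y.size)] + cols) if cols \
        else np.ones((y.size, 1))
    beta, converged, history = _newton_logistic(X, y, tol, max_iter)
    # complete separation: the fitted direction classifies the classes
    # with a clean margin, so the unpenalized MLE diverges
    t_fit = X @ beta
    separated = bool(np.abs(beta).max() > COEF_CAP
                     or (beta[1:].any()
                         and t_fit[y == 1].min() > t_fit[y == 0].max()
                         and np.abs(beta).max() > 5.0))
    if separated:
        converged = False
        if np.abs(beta).max() > COEF_CAP:
            # rescale (not clip componentwise): preserves the decision
            # direction and keeps the linear predictor out of saturation
            beta = beta * (COEF_CAP / np.abs(beta).max())
    # Wald p-values from the observed information
    t = X @ beta
    p = 1.0 / (1.0 + np.exp(-t))
    w = np.maximum(p * (1.0 - p), 1e-12)
    hess = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(beta.size, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    p_values = 2.0 * stats.norm.sf(np.abs(z))
    model = LogisticModel(coefficients=beta, covariates=list(covariates),
                          converged=converged, separated=separated,
                          log_likelihood=history[-1], p_values=p_values,
                          log_scale=log_scale, ll_history=history)
    # AUC and Youden threshold on the linear predictor (rank-equivalent
    # to the probability but immune to sigmoid saturation under
    # separation); the threshold is reported on the probability scale
    t_lin = X @ beta
    model.auc = roc_auc(t_lin, y)[0]
    t_best = _youden_threshold_raw(t_lin, y)
    model.optimal_threshold = float(
        np.clip(1.0 / (1.0 + np.exp(-t_best)), 1e-12, 1.0 - 1e-12))
    return model


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[float]
            ) -> Tuple[float, np.ndarray]:
    """AUC by the rank (Mann-Whitney) formulation with half-credit for
    ties, plus ROC points at every distinct score threshold.

    Returns (auc, points) with points rows (threshold, fpr, tpr).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    pos = y == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both labels must be present")
    ranks = stats.rankdata(s)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    thresholds = np.unique(s)[::-1]
    points = np.empty((thresholds.size + 1, 3))
    points[0] = (np.inf, 0.0, 0.0)
    for i, th in enumerate(thresholds, start=1):
        pred = s >= th
        points[i] = (th, (pred & ~pos).sum() / n0, (pred & pos).sum() / n1)
    return float(auc), points


def _youden_threshold_raw(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = labels == 1
    n1, n0 = pos.sum(), (~pos).sum()
    best_j, best_th = -np.inf, np.nan
    for th in np.sort(np.unique(scores)):          # ties -> lower threshold
        pred = scores >= th
        j = (pred & pos).sum() / n1 + (~pred & ~pos).sum() / n0 - 1.0
        if j > best_j:
            best_j, best_th = j, th
    return float(best_th)


def _youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    return float(np.clip(_youden_threshold_raw(scores, labels),
                         1e-12, 1.0 - 1e-12))


def optimal_threshold(model: LogisticModel, table: pd.DataFrame) -> float:
    """Probability threshold maximizing Youden's J = sens + spec - 1."""
    scores = model.predict_proba(table)
    y = (table["group"].to_numpy() == "aneurysm").astype(float)
    return _youden_threshold(scores, y)


# ---------------------------------------------------------------------------
# quadrant summaries
# ---------------------------------------------------------------------------

def quadrant_summary(table: pd.DataFrame, index: str = "SSI"
                     ) -> pd.DataFrame:
    """Five-number summaries per group x quadrant.

    Quartiles use the linear-interpolation (type-7) quantile rule;
    whiskers extend to the most extreme data point within 1.5*IQR of the
    quartiles.  Empty cells are reported as missing rows with NaN.
    """
    validate_cohort(table)
    rows = []
    for group in GROUPS:
        for quadrant in ("A", "L", "P", "R"):
            sel = table[(table["group"] == group)
                        & (table["quadrant"] == quadrant)][index]
            if sel.empty:
                rows.append({"group": group, "quadrant": quadrant,
                             "median": np.nan, "q1": np.nan, "q3": np.nan,
                             "whisker_lo": np.nan, "whisker_hi": np.nan,
                             "n": 0})
                continue
            v = sel.to_numpy(dtype=float)
            q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
            iqr = q3 - q1
            lo = v[v >= q1 - 1.5 * iqr].min()
            hi = v[v <= q3 + 1.5 * iqr].max()
            rows.append({"group": group, "quadrant": quadrant,
                         "median": med, "q1": q1, "q3": q3,
                         "whisker_lo": lo, "whisker_hi": hi, "n": v.size})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full cohort report
# ---------------------------------------------------------------------------

def cohort_report(table: pd.DataFrame, log_scale: bool = True) -> Dict:
    """Pearson, quadrant summaries, logistic models, ROC/AUC, thresholds."""
    validate_cohort(table)
    for group in GROUPS:
        if (table["group"] == group).sum() < 2:
            raise ValueError(f"need at least 2 observations in '{group}'")
    report: Dict = {"n_observations": int(len(table)),
                    "n_cases": int(table["case_id"].nunique())}
    report["pearson"] = {}
    for index in ("SSI", "dSSI"):
        r, p = pearson_r(table["diameter_mm"], table[index])
        report["pearson"][index] = {"r": r, "p_value": p,
                                    "significant": bool(p < SIGNIFICANCE)}
    report["quadrant_summary"] = {
        index: quadrant_summary(table, index).to_dict(orient="records")
        for index in ("SSI", "dSSI")}
    report["logistic"] = {}
    for name, covs in (("SSI", ["SSI"]), ("dSSI", ["dSSI"]),
                       ("combined", ["SSI", "dSSI"])):
        model = fit_logistic(table, covs, log_scale=log_scale)
        report["logistic"][name] = {
            "coefficients": model.coefficients.tolist(),
            "covariates": model.covariates,
            "log_scale": model.log_scale,
            "converged": model.converged,
            "separated": model.separated,
            "log_likelihood": model.log_likelihood,
            "p_values": model.p_values.tolist(),
            "AUC": model.auc,
            "optimal_threshold": model.optimal_threshold,
        }
    return report
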