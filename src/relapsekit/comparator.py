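"""Naive participant-month logistic baseline.

A deliberately simple comparator: for each participant and each 30-day
enrollment block, a logistic regression on demographics (age, sex,
education), the month's mean medication-adherence survey score, and the
month's mean psychosis survey score predicts whether a relapse occurred
in that block. Evaluation is in-sample (no holdout), per site and
pooled; the pooled fit is an independent run on all sites jointly, not
a sum of the per-site counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import DailyFeatureMatrix

MONTH_DAYS = 30
PREDICTOR_SURVEYS = {"medication": "med_adherence", "psychosis": "psychosis_score"}
COEF_BOUND = 15.0  # |coefficient| beyond this flags quasi-separation


@dataclass
class LogisticFit:
    params: pd.Series
    converged: bool
    n_iter: int
    separation: bool


def monthly_design(
    participants: pd.DataFrame,
    matrices: dict[str, DailyFeatureMatrix],
    relapses: pd.DataFrame,
) -> pd.DataFrame:
    """One row per (participant, enrolled 30-day month).

    Survey predictors are means over the month's observed daily values;
    months with no completed predictor surveys are excluded. The label
    is 1 iff any relapse day falls in the month's block.
    """
    rel_days = relapses.groupby("id")["day"].apply(list) if len(relapses) else {}
    rows = []
    for _, p in participants.iterrows():
        pid = p["id"]
        if pid not in matrices:
            continue
        data = matrices[pid].data
        n_months = int(p["enrollment_days"]) // MONTH_DAYS
        days_rel = rel_days.get(pid, []) if len(relapses) else []
        for m in range(n_months):
            block = data.iloc[m * MONTH_DAYS : (m + 1) * MONTH_DAYS]
            means = {
                col: block[feat].mean() for feat, col in PREDICTOR_SURVEYS.items()
            }
            if any(np.isnan(v) for v in means.values()):
                continue  # no completed surveys for a predictor this month
            label = int(
                any(m * MONTH_DAYS <= d < (m + 1) * MONTH_DAYS for d in days_rel)
            )
            rows.append(
                {
                    "id": pid,
                    "site": p["site"],
                    "month": m,
                    "age": float(p["age"]),
                    "sex": p["sex"],
                    "education": p["education"],
                    **means,
                    "label": label,
                }
            )
    cols = ["id", "site", "month", "age", "sex", "education",
            "med_adherence", "psychosis_score", "label"]
    return pd.DataFrame(rows, columns=cols)


def _design_matrix(table: pd.DataFrame) -> pd.DataFrame:
    X = table[["age", "med_adherence", "psychosis_score"]].astype(float).copy()
    for cat in ("sex", "education"):
        dummies = pd.get_dummies(table[cat], prefix=cat, drop_first=True, dtype=float)
        X = pd.concat([X, dummies], axis=1)
    X.insert(0, "intercept", 1.0)
    return X


def fit_logistic(table: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic fit (IRLS via statsmodels GLM).

    Raises on a constant label; quasi-separation is flagged and the
    diverging coefficients are clipped at +/-15 with a warning.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 participant-months to fit")
    y = table["label"].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("degenerate outcome: label is constant")
    X = _design_matrix(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
        res = model.fit(maxiter=200, tol=1e-10)
    params = pd.Series(res.params, index=X.columns)
    separation = bool((params.abs() > COEF_BOUND).any())
    if separation:
        warnings.warn("quasi-separation detected; coefficients clipped at bound")
        # rescale the whole vector: positive scaling preserves the
        # 0.5-threshold decision boundary while bounding magnitudes
        params = params * (COEF_BOUND / params.abs().max())
    return LogisticFit(params, bool(res.converged), int(res.fit_history["iteration"]),
                       separation)


def predict_probabilities(fit: LogisticFit, table: pd.DataFrame) -> np.ndarray:
    X = _design_matrix(table)
    X = X.reindex(columns=fit.params.index, fill_value=0.0)
    eta = X.to_numpy() @ fit.params.to_numpy()
    return 1.0 / (1.0 + np.exp(-eta))


def predict_relapse_months(
    fit: LogisticFit, table: pd.DataFrame, threshold: float = 0.5
) -> dict[str, int]:
    """Confusion counts at participant-month units (predicted = prob > threshold)."""
    prob = predict_probabilities(fit, table)
    pred = prob > threshold
    y = table["label"].to_numpy(dtype=int) == 1
    return {
        "TP": int((pred & y).sum()),
        "FP": int((pred & ~y).sum()),
        "TN": int((~pred & ~y).sum()),
        "FN": int((~pred & y).sum()),
    }


def evaluate_comparator(
    table: pd.DataFrame, threshold: float = 0.5
) -> dict[str, dict]:
    """Per-site and pooled fits with month-level confusion counts.

    The "Total" entry refits on all sites jointly. Sites where the fit
    is degenerate (constant label) report counts of all-negative
    predictions against the observed labels.
    """
    out = {}
    sites = list(dict.fromkeys(table["site"]))
    for name, sub in [(s, table[table["site"] == s]) for s in sites] + [
        ("Total", table)
    ]:
        try:
            fit = fit_logistic(sub)
            counts = predict_relapse_months(fit, sub, threshold)
        except ValueError:
            y = sub["label"].to_numpy(dtype=int)
            counts = {"TP": 0, "FP": 0, "TN": int((y == 0).sum()),
                      "FN": int((y == 1).sum())}
            fit = None
        counts["n_months"] = int(len(sub))
        out[name] = {"counts": counts, "fit": fit}
    return out


def month_rate_ratio(
    table: pd.DataFrame,
    threshold: float | None = None,
    fit: LogisticFit | None = None,
) -> float:
    """How much more often the baseline predicts positives in relapse
    months than in other months (rate ratio; NaN if undefined).

    With ``threshold=None`` the call threshold is the label prevalence:
    at a few-percent base rate an in-sample-calibrated model crosses 0.5
    almost never, which would leave the enrichment comparison degenerate
    (zero or a handful of calls), so the comparison is made where the
    comparator actually commits to calls.
    """
    fit = fit or fit_logistic(table)
    if threshold is None:
        threshold = float(table["label"].mean())
    pred = predict_probabilities(fit, table) > threshold
    y = table["label"].to_numpy(dtype=int) == 1
    if y.sum() == 0 or (~y).sum() == 0:
        return float("nan")
    inside = pred[y].mean()
    outside = pred[~y].mean()
    if outside == 0:
        return float("inf") if inside > 0 else float("nan")
    return float(inside / outside)
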