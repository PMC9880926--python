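"""PELT changepoint detection with an L2 cost, and survey correlations.

Segments each passive daily stream by exactly minimizing

    sum over segments of within-segment squared deviation  +  beta * (#changepoints)

via the PELT dynamic program (pruning is lossless for the L2 cost).
Missing days are compressed out before segmentation and the reported
indices are mapped back to the original day axis. Changepoint presence
within +/-10 days of a monthly questionnaire is then correlated with
the survey score (Pearson r, two-sided p from the t transform).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class ChangepointSet:
    participant_id: str
    stream: str
    penalty: float
    changepoints: list[int]  # original-axis day index of each new segment start
    n_days: int


@dataclass
class CorrelationResult:
    stream: str
    instrument: str
    r: float
    p: float
    n: int


def default_penalty(series: np.ndarray) -> float:
    """BIC-like penalty 2 * sigma^2 * log(n), sigma robustly estimated
    from first differences (MAD-based, so level shifts barely bias it)."""
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        return 1.0
    d = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2)
    if sigma == 0:
        sigma = np.std(d) / np.sqrt(2) or 1.0
    return float(2.0 * sigma**2 * np.log(n))


def pelt_l2(
    series, beta: float, participant_id: str = "", stream: str = ""
) -> ChangepointSet:
    """Exact penalized L2 segmentation of a (possibly gappy) series.

    beta = 0 places a changepoint at every observed index; beta -> inf
    yields a single segment. Returns 0-based original-axis indices of
    each new segment's first day, strictly inside (0, n).
    """
    x = np.asarray(series, dtype=float)
    n_days = len(x)
    obs = np.flatnonzero(~np.isnan(x))
    y = x[obs]
    m = len(y)
    if m < 2:
        warnings.warn(
            f"series {participant_id}/{stream}: fewer than 2 observed points; "
            "no segmentation performed"
        )
        return ChangepointSet(participant_id, stream, float(beta), [], n_days)
    if beta < 0:
        raise ValueError("penalty beta must be >= 0")

    s1 = np.concatenate([[0.0], np.cumsum(y)])
    s2 = np.concatenate([[0.0], np.cumsum(y**2)])

    def seg_cost(i: int, j: int) -> float:  # cost of y[i:j]
        d = j - i
        return s2[j] - s2[i] - (s1[j] - s1[i]) ** 2 / d

    F = np.empty(m + 1)
    F[0] = -beta
    last = np.zeros(m + 1, dtype=int)
    cand = [0]
    for t in range(1, m + 1):
        vals = [F[s] + seg_cost(s, t) + beta for s in cand]
        k = int(np.argmin(vals))
        F[t] = vals[k]
        last[t] = cand[k]
        # lossless pruning for subadditive (here: zero-K) L2 cost
        cand = [s for s, v in zip(cand, vals) if v - beta <= F[t]]
        cand.append(t)

    cps_compressed = []
    t = m
    while t > 0:
        s = last[t]
        if s > 0:
            cps_compressed.append(s)
        t = s
    cps_compressed.reverse()
    cps = [int(obs[s]) for s in cps_compressed]
    return ChangepointSet(participant_id, stream, float(beta), cps, n_days)


def cp_within_window(cps: ChangepointSet, survey_day: int, w: int = 10) -> int:
    """1 iff any changepoint lies within ``w`` days of ``survey_day`` (inclusive)."""
    return int(any(abs(d - survey_day) <= w for d in cps.changepoints))


def cp_survey_correlation(indicators, scores) -> CorrelationResult:
    """Pearson r between a 0/1 changepoint-presence sequence and scores."""
    ind = np.asarray(indicators, dtype=float)
    sc = np.asarray(scores, dtype=float)
    keep = ~(np.isnan(ind) | np.isnan(sc))
    ind, sc = ind[keep], sc[keep]
    if len(ind) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(ind) == 0 or np.ptp(sc) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = stats.pearsonr(ind, sc)
    return CorrelationResult("", "", float(r), float(p), int(len(ind)))


def changepoint_survey_matrix(
    cps_by_stream: dict[str, dict[str, ChangepointSet]],
    monthly: pd.DataFrame,
    w: int = 10,
    use_score_change: bool = False,
) -> pd.DataFrame:
    """Stream x instrument correlation table (r, raw p, BH q, n).

    For every participant visit, pairs the survey score (or its change
    from the previous visit when ``use_score_change``) with an indicator
    of a changepoint within ``w`` days of the visit day (visit index *
    30). The Benjamini-Hochberg q column is an extension beyond the raw
    p-value display.
    """
    rows = []
    for stream, by_pid in cps_by_stream.items():
        for inst, grp in monthly.groupby("instrument"):
            ind, val = [], []
            for pid, sub in grp.groupby("id"):
                if pid not in by_pid:
                    continue
                sub = sub.sort_values("visit")
                scores = sub["score"].to_numpy(dtype=float)
                visits = sub["visit"].to_numpy(dtype=int)
                series = scores if not use_score_change else np.r_[np.nan, np.diff(scores)]
                for v, s in zip(visits, series):
                    if np.isnan(s):
                        continue
                    ind.append(cp_within_window(by_pid[pid], int(v) * 30, w))
                    val.append(float(s))
            try:
                res = cp_survey_correlation(ind, val)
                rows.append(
                    {"stream": stream, "instrument": inst,
                     "r": res.r, "p": res.p, "n": res.n}
                )
            except ValueError:
                rows.append(
                    {"stream": stream, "instrument": inst,
                     "r": np.nan, "p": np.nan, "n": len(val)}
                )
    out = pd.DataFrame(rows, columns=["stream", "instrument", "r", "p", "n"])
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out[["stream", "instrument", "r", "p", "q", "n"]]
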