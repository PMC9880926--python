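"""Headline evaluation statistics.

Windowed confusion matrices at (day x channel) units, summary metrics
(RMSE / sensitivity / specificity), anomaly-rate enrichment around
relapses, relapse labeling from monthly PANSS scores, the site
chi-square, the Freeman-Halton exact test, and the cross-site
control-FPR permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TP_WINDOW_DAYS = 30


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    unit: str = "day_channel"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    rmse: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 3) -> dict[str, float]:
        return {
            "rmse": round(self.rmse, ndigits),
            "sensitivity": round(self.sensitivity, ndigits),
            "specificity": round(self.specificity, ndigits),
        }


@dataclass(frozen=True)
class RateRatioResult:
    mode: str  # pre | pre_post
    rate_inside: float
    rate_outside: float
    ratio: float
    n_inside: int
    n_outside: int
    diagnostic: str = ""


@dataclass(frozen=True)
class PermutationResult:
    site_areas: dict[str, float]
    observed_spread: float
    n_perm: int
    seed: int
    p: float
    statistic: str = "range"


def binary_metrics(c: ConfusionCounts) -> MetricSet:
    """rmse = sqrt((FP+FN)/n); sensitivity = TP/(TP+FN); specificity = TN/(TN+FP).

    A zero denominator marks the metric undefined (NaN + flag), never 0.
    """
    undefined = []
    n = c.total
    if n > 0:
        rmse = math.sqrt((c.fp + c.fn) / n)
    else:
        rmse, undefined = float("nan"), undefined + ["rmse"]
    if c.tp + c.fn > 0:
        sens = c.tp / (c.tp + c.fn)
    else:
        sens, undefined = float("nan"), undefined + ["sensitivity"]
    if c.tn + c.fp > 0:
        spec = c.tn / (c.tn + c.fp)
    else:
        spec, undefined = float("nan"), undefined + ["specificity"]
    return MetricSet(rmse, sens, spec, tuple(undefined))


def _window_days(day: int, window: int, mode: str) -> tuple[int, int]:
    if mode == "pre":
        return day - window, day - 1  # relapse day itself excluded
    return day - window, day + window


def _in_any_window(days: np.ndarray, rel_days: list[int], lo_hi) -> np.ndarray:
    mask = np.zeros(len(days), dtype=bool)
    for d in rel_days:
        lo, hi = lo_hi(d)
        mask |= (days >= lo) & (days <= hi)
    return mask


def confusion_at_window(
    anomalies: pd.DataFrame,
    relapses: pd.DataFrame,
    window: int = TP_WINDOW_DAYS,
) -> ConfusionCounts:
    """Windowed confusion over every scored (participant, day, channel).

    A flag within +/-window of any of the participant's relapses is a
    TP; a flag outside all windows an FP; an unflagged in-window scored
    unit an FN; everything else a TN.
    """
    rel = relapses.groupby("id")["day"].apply(list) if len(relapses) else {}
    tp = fp = tn = fn = 0
    for pid, sub in anomalies.groupby("id"):
        days = sub["day"].to_numpy(dtype=int)
        flags = sub["flag"].to_numpy(dtype=bool)
        rel_days = rel.get(pid, []) if len(relapses) else []
        inwin = _in_any_window(days, rel_days, lambda d: (d - window, d + window))
        tp += int((flags & inwin).sum())
        fp += int((flags & ~inwin).sum())
        fn += int((~flags & inwin).sum())
        tn += int((~flags & ~inwin).sum())
    return ConfusionCounts(tp, fp, tn, fn, unit="day_channel")


def rate_ratio(
    anomalies: pd.DataFrame,
    relapses: pd.DataFrame,
    mode: str = "pre",
    window: int = TP_WINDOW_DAYS,
) -> RateRatioResult:
    """Flag-rate enrichment inside relapse windows vs outside.

    mode="pre": windows are the 30 days before each relapse (exclusive
    of the relapse day); mode="pre_post": 30 days either side. Rates are
    per scored (day, channel) unit, so missing days never enter either
    denominator.
    """
    if mode not in ("pre", "pre_post"):
        raise ValueError("mode must be 'pre' or 'pre_post'")
    rel = relapses.groupby("id")["day"].apply(list) if len(relapses) else {}
    fin = nin = fout = nout = 0
    for pid, sub in anomalies.groupby("id"):
        days = sub["day"].to_numpy(dtype=int)
        flags = sub["flag"].to_numpy(dtype=bool)
        rel_days = rel.get(pid, []) if len(relapses) else []
        inwin = _in_any_window(days, rel_days, lambda d: _window_days(d, window, mode))
        fin += int(flags[inwin].sum())
        nin += int(inwin.sum())
        fout += int(flags[~inwin].sum())
        nout += int((~inwin).sum())
    if nout == 0:
        raise ValueError("no scored units outside relapse windows")
    rate_out = fout / nout
    rate_in = fin / nin if nin else float("nan")
    if rate_out == 0:
        return RateRatioResult(mode, rate_in, 0.0, float("nan"), nin, nout,
                               diagnostic="zero outside-window rate")
    return RateRatioResult(mode, rate_in, rate_out, rate_in / rate_out, nin, nout)


def relapse_from_panss(monthly: pd.DataFrame) -> pd.DataFrame:
    """Label a relapse at visit t iff PANSS_t >= 1.25 * PANSS at the
    previous non-missing visit (boundary inclusive); missing visits are
    skipped, not treated as breaks. Event day = visit index * 30."""
    rows = []
    panss = monthly[monthly["instrument"] == "PANSS"]
    for pid, sub in panss.groupby("id"):
        sub = sub.sort_values("visit").dropna(subset=["score"])
        scores = sub["score"].to_numpy(dtype=float)
        visits = sub["visit"].to_numpy(dtype=int)
        for i in range(1, len(scores)):
            if scores[i] >= 1.25 * scores[i - 1]:
                rows.append(
                    {"id": pid, "day": int(visits[i]) * 30,
                     "criterion": "panss_25pct"}
                )
    return pd.DataFrame(rows, columns=["id", "day", "criterion"])


def site_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a site x outcome table."""
    t = np.asarray(table, dtype=float)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


# ---------------------------------------------------------------------------
# Freeman-Halton exact test

_ENUM_MAX_DIM = 4
_ENUM_MAX_TOTAL = 200


def _table_logp(flat, lr, lc, ln):
    return lr + lc - ln - sum(math.lgamma(v + 1) for v in flat)


def _row_fills(target: int, col_rem: np.ndarray):
    """All ways to fill one row summing to ``target`` within column remainders."""
    C = len(col_rem)
    suffix = np.concatenate([np.cumsum(col_rem[::-1])[::-1][1:], [0]])

    def rec(c: int, rem: int, acc: tuple):
        if c == C - 1:
            if rem <= col_rem[c]:
                yield acc + (rem,)
            return
        lo = max(0, rem - int(suffix[c]))
        for v in range(lo, min(rem, int(col_rem[c])) + 1):
            yield from rec(c + 1, rem - v, acc + (v,))

    yield from rec(0, int(target), ())


def _enumerate_p(rows: np.ndarray, cols: np.ndarray, lp_obs: float) -> float:
    """Sum multivariate-hypergeometric probabilities of all tables with
    fixed margins whose probability <= the observed table's."""
    lr = sum(math.lgamma(r + 1) for r in rows)
    lc = sum(math.lgamma(c + 1) for c in cols)
    ln = math.lgamma(rows.sum() + 1)
    R = len(rows)
    p_acc = 0.0

    def rec(r: int, col_rem: np.ndarray, lp_cells: float):
        nonlocal p_acc
        if r == R - 1:
            # last row forced by the column margins
            lp = lr + lc - ln - lp_cells - sum(
                math.lgamma(v + 1) for v in col_rem
            )
            if lp <= lp_obs + 1e-9:
                p_acc += math.exp(lp)
            return
        for fill in _row_fills(rows[r], col_rem):
            rec(
                r + 1,
                col_rem - np.array(fill),
                lp_cells + sum(math.lgamma(v + 1) for v in fill),
            )

    rec(0, cols.astype(int).copy(), 0.0)
    return p_acc


def freeman_halton(
    table,
    monte_carlo: int | None = None,
    seed: int | None = None,
) -> float:
    """Exact conditional p-value for an r x c contingency table.

    All-zero rows/columns are dropped; a single remaining row or column
    gives p = 1. Full enumeration is used up to 4 x 4 and total 200;
    larger tables require ``monte_carlo`` (seeded table sampling with
    fixed margins), otherwise a ValueError advises it.
    """
    t = np.asarray(table, dtype=int)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] <= 1 or t.shape[1] <= 1:
        return 1.0
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    lr = sum(math.lgamma(r + 1) for r in rows)
    lc = sum(math.lgamma(c + 1) for c in cols)
    ln = math.lgamma(t.sum() + 1)
    lp_obs = _table_logp(t.ravel(), lr, lc, ln)
    if monte_carlo is not None:
        rng = np.random.default_rng(seed)
        dist = stats.random_table(rows, cols)
        samples = dist.rvs(monte_carlo, random_state=rng)
        samples = samples.reshape(monte_carlo, *t.shape)
        lps = np.array([_table_logp(s.ravel(), lr, lc, ln) for s in samples])
        return float(np.mean(lps <= lp_obs + 1e-9))
    if max(t.shape) > _ENUM_MAX_DIM or t.sum() > _ENUM_MAX_TOTAL:
        raise ValueError(
            "table too large for exact enumeration; pass monte_carlo=<n> "
            "(seeded) for a Monte-Carlo p-value"
        )
    return float(min(_enumerate_p(rows, cols, lp_obs), 1.0))


# ---------------------------------------------------------------------------
# control-FPR curves and the cross-site permutation test


def fpr_grid(n: int = 50, lo: float = 1e-4, hi: float = 0.05) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), n)


def control_fpr_auc(
    pvalues_by_site: dict[str, dict[str, np.ndarray]],
    grid: np.ndarray | None = None,
    fpr_cap: float = 0.25,
) -> dict[str, float]:
    """Truncated area under each site's control FPR-vs-cutoff curve.

    FPR(c) = fraction of the site's scored control day-channels with
    p <= c over a fixed logspaced cutoff grid; the trapezoid area over
    grid points with FPR <= cap is normalized by the grid span. Sites
    with no controls are excluded.
    """
    grid = fpr_grid() if grid is None else np.asarray(grid)
    out = {}
    for site, pv in pvalues_by_site.items():
        arrs = [np.asarray(a) for a in pv.values() if len(a)]
        if not arrs:
            continue
        pooled = np.concatenate(arrs)
        fpr = (pooled[:, None] <= grid).mean(axis=0)
        out[site] = _area(fpr, grid, fpr_cap)
    return out


def _area(fpr: np.ndarray, grid: np.ndarray, cap: float) -> float:
    keep = fpr <= cap
    if keep.sum() < 2:
        return 0.0
    return float(np.trapezoid(fpr[keep], grid[keep]) / (grid[-1] - grid[0]))


def permutation_site_test(
    pvalues_by_site: dict[str, dict[str, np.ndarray]],
    n_perm: int = 1000,
    seed: int = 0,
    grid: np.ndarray | None = None,
    fpr_cap: float = 0.25,
    statistic: str = "range",
) -> PermutationResult:
    """Permute control participants' site labels and compare area spreads.

    The observed statistic is the spread (range by default, variance as
    an alternative) of per-site truncated FPR areas; site labels are
    permuted at the participant level preserving per-site counts, and
    p is the proportion of permuted spreads >= the observed spread
    (at-least-as-extreme; no add-one correction).
    """
    sites = sorted(s for s in pvalues_by_site if pvalues_by_site[s])
    if len(sites) < 2:
        raise ValueError("need controls at >= 2 sites")
    grid = fpr_grid() if grid is None else np.asarray(grid)

    pids, labels, counts, totals = [], [], [], []
    for si, site in enumerate(sites):
        for pid, arr in sorted(pvalues_by_site[site].items()):
            arr = np.asarray(arr, dtype=float)
            pids.append(pid)
            labels.append(si)
            counts.append((arr[:, None] <= grid).sum(axis=0))
            totals.append(len(arr))
    labels = np.array(labels)
    counts = np.array(counts, dtype=float)
    totals = np.array(totals, dtype=float)

    def spread(lab: np.ndarray) -> tuple[float, dict[str, float]]:
        areas = {}
        for si, site in enumerate(sites):
            sel = lab == si
            fpr = counts[sel].sum(axis=0) / totals[sel].sum()
            areas[site] = _area(fpr, grid, fpr_cap)
        vals = np.array(list(areas.values()))
        stat = float(vals.max() - vals.min()) if statistic == "range" else float(
            vals.var()
        )
        return stat, areas

    obs_spread, obs_areas = spread(labels)
    rng = np.random.default_rng(seed)
    perm_spreads = np.empty(n_perm)
    for b in range(n_perm):
        perm_spreads[b] = spread(rng.permutation(labels))[0]
    p = float(np.mean(perm_spreads >= obs_spread))
    return PermutationResult(obs_areas, obs_spread, n_perm, seed, p, statistic)


# ---------------------------------------------------------------------------
# worked-example arithmetic


def true_positive_percent(tp: int, total_flags: int) -> float:
    """Percent of flagged anomalies that are true positives."""
    if total_flags <= 0:
        raise ValueError("total_flags must be > 0")
    return 100.0 * tp / total_flags


def relative_effectiveness(anomaly_ratio: float, naive_ratio: float) -> float:
    """Quotient of the two models' enrichment ratios."""
    if naive_ratio == 0:
        raise ValueError("naive ratio must be nonzero")
    return anomaly_ratio / naive_ratio
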