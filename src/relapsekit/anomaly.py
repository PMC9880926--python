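"""Daily multivariate anomaly p-values per collection channel.

Each participant-day, per channel, is scored against a local Gaussian
model of temporally nearby days: a kernel-weighted mean and covariance
over a +/-W day reference window (excluding the day itself), a squared
Mahalanobis distance of the day's observed sub-vector, and an upper-tail
p-value. Days with p <= alpha (default 0.005) are formal anomalies.

The tail is calibrated for the finite reference sample. When the
kernel-weighted pairwise overlap can support a covariance estimate,
the squared Mahalanobis distance is referred to the Hotelling
T-squared -> F transform with the minimum pairwise Kish effective
sample size as the Wishart degrees of freedom; when missingness makes
the pairwise overlap too thin (common for sparse survey channels),
each observed feature's residual is normalized exactly through a
Student-t -> normal score and the sum of squared scores is referred to
chi-squared, ignoring cross-feature correlation. A naive chi-squared
tail on the full-covariance distance is available via
``AnomalyParams.tail = "chi2"``. Calibration is exact-to-excellent for
independent or fully observed features; heavily missing *and* strongly
correlated features yield approximate p-values (see docs/methods.md).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DailyFeatureMatrix
from .streams import CHANNEL_FEATURES, CHANNELS, FEATURE_GROUP, GROUP_ORDER

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnomalyParams:
    """Tunables of the local anomaly model.

    window: reference half-width W in days.
    bandwidth: Gaussian kernel bandwidth h in days.
    ridge: covariance conditioning floor added to the diagonal (applied
        after standardization, so it is in squared-SD units).
    alpha: significance cutoff for formal anomalies.
    min_ref_days: fewer usable reference days than this -> no p-value.
    tail: "f" (finite-sample calibrated, default) or "chi2".
    """

    window: int = 30
    bandwidth: float = 10.0
    ridge: float = 1e-6
    alpha: float = 0.005
    min_ref_days: int = 5
    tail: str = "f"

    def __post_init__(self):
        if self.window < 5:
            raise ValueError("window must be >= 5 days")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.ridge <= 0:
            raise ValueError("ridge must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.tail not in ("f", "chi2"):
            raise ValueError("tail must be 'f' or 'chi2'")


@dataclass
class AnomalySeries:
    """Per-day p-values for one participant and channel.

    ``table`` has one row per scored day (days with no observed channel
    feature are absent): columns p, d2, n_features. ``zscores`` holds
    the locally standardized deviations used for attribution.
    """

    participant_id: str
    channel: str
    table: pd.DataFrame
    zscores: pd.DataFrame
    alpha: float = 0.005

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"]

    def flags(self, alpha: float | None = None) -> list[int]:
        return flag_anomalies(self, self.alpha if alpha is None else alpha)


#: a feature needs this much effective reference weight to be scored
_MIN_FEATURE_ESS = 2.5
#: min pairwise ESS margin (over df) required for the full-covariance path
_PAIR_ESS_MARGIN = 2.0
#: reference cells beyond this many robust SDs (median/MAD scale) are
#: trimmed before the moment pass, so nearby outliers cannot mask the
#: day being scored
_TRIM_Z = 3.0
#: variance consistency constant for Gaussian truncation at _TRIM_Z:
#: E[z^2 | |z| < a]
_TRIM_C = 1.0 - 2 * _TRIM_Z * stats.norm.pdf(_TRIM_Z) / (
    2 * stats.norm.cdf(_TRIM_Z) - 1
)
_MAD_TO_SD = 1.4826


def _weighted_local_moments(Z: np.ndarray, w: np.ndarray):
    """Kernel-weighted moments with pairwise-complete missing data.

    Returns (mu, S, var_jj, neff_j, ess_pair, n_usable_rows): weighted
    mean, pairwise covariance (unbiased normalization), per-feature
    variances, per-feature Kish effective sample sizes, pairwise Kish
    ESS matrix, and the number of reference days with any data.
    """
    mask = ~np.isnan(Z)
    Zf = np.where(mask, Z, 0.0)
    Wm = w[:, None] * mask
    sw = Wm.sum(axis=0)
    sw2 = ((w**2)[:, None] * mask).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(sw > 0, (Wm * Zf).sum(axis=0) / sw, np.nan)
        neff_j = np.where(sw2 > 0, sw**2 / sw2, 0.0)
    D = np.where(mask, Zf - np.where(np.isnan(mu), 0.0, mu), 0.0)
    num = (w[:, None] * D).T @ D
    Npair = (w[:, None] * mask).T @ mask
    Qpair = ((w**2)[:, None] * mask).T @ mask
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = Npair - Qpair / Npair
        S = np.where(denom > 0, num / denom, 0.0)
        ess_pair = np.where(Qpair > 0, Npair**2 / Qpair, 0.0)
    return mu, S, np.diag(S).copy(), neff_j, ess_pair, int(mask.any(axis=1).sum())


def _full_cov_d2(resid: np.ndarray, S: np.ndarray, ridge: float) -> float:
    f = len(resid)
    evals, evecs = np.linalg.eigh(S + ridge * np.eye(f))
    evals = np.maximum(evals, max(ridge, 1e-10 * float(evals.max())))
    return float(resid @ (evecs @ ((evecs.T @ resid) / evals)))


def flag_threshold_d2(alpha: float, f: int, m_ess: float, tail: str = "f") -> float:
    """Squared-distance cutoff equivalent to p <= alpha (inverse tail).

    ``m_ess`` is the effective sample size behind the covariance; when
    it cannot support the F reference (or tail="chi2") the chi-squared
    cutoff applies, matching the scorer's fallback.
    """
    if tail == "f" and m_ess - f >= _PAIR_ESS_MARGIN + 1:
        m = m_ess - 1.0
        return float(
            stats.f.isf(alpha, f, m - f + 1) * (m * f) / (m - f + 1) * (1 + 1 / m_ess)
        )
    return float(stats.chi2.isf(alpha, f))


def kernel_ess(window: int, bandwidth: float) -> float:
    """Kish effective sample size of the interior-day kernel weights."""
    k = np.arange(-window, window + 1)
    w = np.exp(-0.5 * (k / bandwidth) ** 2)
    w = w[k != 0]
    return float(w.sum() ** 2 / (w**2).sum())


def daily_pvalues(
    matrix: DailyFeatureMatrix, params: AnomalyParams | None = None
) -> dict[str, AnomalySeries]:
    """Score every day of one participant, per channel.

    Features are standardized per participant (so output is invariant
    to affine rescaling of any input feature); the local model then
    operates on the standardized matrix.
    """
    params = params or AnomalyParams()
    out: dict[str, AnomalySeries] = {}
    for ch in CHANNELS:
        X = matrix.channel(ch).to_numpy(dtype=float)
        out[ch] = _score_channel(matrix.participant_id, ch, X, params)
    return out


def _score_channel(
    pid: str, channel: str, X: np.ndarray, params: AnomalyParams
) -> AnomalySeries:
    n, f_all = X.shape
    feats = list(CHANNEL_FEATURES[channel])
    # per-participant standardization
    with np.errstate(invalid="ignore"):
        mu_g = np.nanmean(X, axis=0)
        sd_g = np.nanstd(X, axis=0, ddof=1)
    sd_g = np.where((sd_g > 0) & np.isfinite(sd_g), sd_g, 1.0)
    Z = (X - mu_g) / sd_g

    days, ps, d2s, dfs = [], [], [], []
    zrows = {}
    for t in range(n):
        obs = ~np.isnan(Z[t])
        if not obs.any():
            continue  # all-missing day: no entry
        lo, hi = max(0, t - params.window), min(n, t + params.window + 1)
        idx = np.r_[lo:t, t + 1 : hi]
        w = np.exp(-0.5 * ((idx - t) / params.bandwidth) ** 2)
        R = Z[np.ix_(idx, np.flatnonzero(obs))]
        # robust trim: center and scale each feature by median/MAD of
        # the reference window, drop cells beyond _TRIM_Z, and restore
        # the variance scale with the Gaussian truncation constant
        with np.errstate(invalid="ignore", all="ignore"):
            med = np.nanmedian(R, axis=0)
            mad = np.nanmedian(np.abs(R - med), axis=0) * _MAD_TO_SD
            mad = np.where(mad > 0, mad, np.inf)  # degenerate scale: trim nothing
            u0 = np.abs(R - med) / mad
        R_t = np.where(u0 > _TRIM_Z, np.nan, R)
        mu, S, var_jj, neff_j, ess_pair, n_usable = _weighted_local_moments(R_t, w)
        S = S / _TRIM_C
        var_jj = var_jj / _TRIM_C
        if n_usable < params.min_ref_days:
            log.debug("day %d (%s/%s): insufficient reference data", t, pid, channel)
            continue
        # score only features with enough effective reference weight
        good = (neff_j > _MIN_FEATURE_ESS) & (var_jj > 0) & ~np.isnan(mu)
        if not good.any():
            continue
        sel = np.flatnonzero(good)
        fobs = len(sel)
        resid = Z[t, np.flatnonzero(obs)][sel] - mu[sel]
        m_all = float(ess_pair[np.ix_(sel, sel)].min())
        if (
            params.tail == "f"
            and fobs > 1
            and m_all >= fobs + _PAIR_ESS_MARGIN + 1
        ):
            # full-covariance path: Hotelling T^2 -> F with pairwise ESS dof
            d2 = _full_cov_d2(resid, S[np.ix_(sel, sel)], params.ridge)
            m = m_all - 1.0
            fstat = (m - fobs + 1) / (m * fobs) * d2 / (1.0 + 1.0 / m_all)
            p = float(stats.f.sf(fstat, fobs, m - fobs + 1))
        elif params.tail == "f":
            # sparse path: exact marginal t -> normal scores, correlation
            # ignored (see module docstring)
            nj = neff_j[sel]
            u = resid / np.sqrt(var_jj[sel] * (1.0 + 1.0 / nj))
            zt = stats.norm.ppf(
                np.clip(stats.t.cdf(u, nj - 1.0), 1e-15, 1 - 1e-15)
            )
            d2 = float((zt**2).sum())
            p = float(stats.chi2.sf(d2, fobs))
        else:
            d2 = _full_cov_d2(resid, S[np.ix_(sel, sel)], params.ridge)
            p = float(stats.chi2.sf(d2, fobs))
        days.append(t)
        ps.append(max(p, np.finfo(float).tiny))
        d2s.append(d2)
        dfs.append(fobs)
        zfull = np.full(f_all, np.nan)
        zfull[np.flatnonzero(obs)[sel]] = resid / np.sqrt(var_jj[sel])
        zrows[t] = zfull
    table = pd.DataFrame(
        {"p": ps, "d2": d2s, "n_features": dfs},
        index=pd.Index(days, name="day"),
    )
    zscores = pd.DataFrame.from_dict(zrows, orient="index", columns=feats)
    zscores.index.name = "day"
    return AnomalySeries(pid, channel, table, zscores, params.alpha)


def flag_anomalies(series: AnomalySeries, alpha: float = 0.005) -> list[int]:
    """Days whose p-value is at or below ``alpha`` (boundary inclusive)."""
    t = series.table
    return [int(d) for d in t.index[t["p"] <= alpha]]


def attribute(series: AnomalySeries, day: int) -> list[str]:
    """Feature groups ranked by max |z| among the day's observed members.

    Ties break deterministically by the canonical group order.
    """
    if day not in series.zscores.index:
        raise KeyError(f"day {day} has no p-value in this series")
    z = series.zscores.loc[day].abs()
    scores = {}
    for g in GROUP_ORDER:
        members = [f for f in z.index if FEATURE_GROUP[f] == g]
        vals = z[members].dropna()
        if len(vals):
            scores[g] = float(vals.max())
    order = {g: i for i, g in enumerate(GROUP_ORDER)}
    return sorted(scores, key=lambda g: (-scores[g], order[g]))


def anomalies_table(
    all_series: dict[str, dict[str, AnomalySeries]], alpha: float = 0.005
) -> pd.DataFrame:
    """Pooled long table: id, channel, day, p, flag, top_group."""
    rows = []
    for pid, by_channel in all_series.items():
        for ch, s in by_channel.items():
            for day in s.table.index:
                p = float(s.table.loc[day, "p"])
                rows.append(
                    {
                        "id": pid,
                        "channel": ch,
                        "day": int(day),
                        "p": p,
                        "flag": p <= alpha,
                        "top_group": attribute(s, day)[0],
                    }
                )
    return pd.DataFrame(rows, columns=["id", "channel", "day", "p", "flag", "top_group"])
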