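"""Synthetic multi-site digital-phenotyping cohorts.

Generates cohorts with the statistical structure the downstream analysis
assumes: per-site R/NR/C composition, truncated-normal enrollment spans,
daily AR(1) feature streams with Bernoulli missingness, computed
data-quality channels, monthly clinical assessments, and relapse events
with an injected behavioral signature (mean shift plus variance
inflation) that gives the anomaly and changepoint stages a recoverable
ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .streams import (
    ACTIVE_FEATURES,
    ALL_FEATURES,
    CHANNEL_FEATURES,
    FEATURE_CHANNEL,
    GROUPS,
    MONTHLY_INSTRUMENTS,
    PANSS_MAX,
    PANSS_MIN,
    PASSIVE_FEATURES,
    RELAPSE_CRITERIA,
    SITES,
)


class ConfigError(ValueError):
    """Raised when a cohort configuration field is invalid."""


@dataclass(frozen=True)
class StreamSpec:
    """Baseline distribution of one daily feature: AR(1) around a mean."""

    mean: float
    sd: float
    phi: float = 0.3  # lag-1 autocorrelation

    def validate(self, name: str) -> None:
        if self.sd <= 0:
            raise ConfigError(f"stream_specs[{name}].sd must be > 0")
        if not abs(self.phi) < 1:
            raise ConfigError(f"stream_specs[{name}].phi must satisfy |phi| < 1")


#: default daily streams (survey scores in instrument units, durations in hours)
DEFAULT_STREAM_SPECS = {
    "phq9": StreamSpec(8.0, 4.0),
    "gad7": StreamSpec(6.0, 3.5),
    "psychosis": StreamSpec(10.0, 4.0),
    "sociability": StreamSpec(12.0, 5.0),
    "sleep_survey": StreamSpec(7.0, 3.0),
    "medication": StreamSpec(2.5, 1.0),
    "sleep_duration": StreamSpec(7.5, 1.5),
    "home_time": StreamSpec(16.0, 4.0),
    "screen_duration": StreamSpec(4.5, 2.0),
}


@dataclass(frozen=True)
class RelapseEffect:
    """Behavioral signature injected around a relapse day.

    Two components, matching how relapse shows up in the two detection
    stages. A *sustained* component: per-feature mean shifts (units of
    the feature's baseline SD) on days within ``window_days`` of the
    event, with within-window variation rescaled about the window mean
    by ``variance_inflation`` — this is what a changepoint detector
    sees. An *acute* component: each in-window day is independently a
    crisis day with probability ``spike_rate``, on which each shifted
    feature independently (probability ``spike_feature_prob``) deviates
    by ``spike_scale`` SDs with random sign — sharp single-day
    excursions that a local anomaly detector sees but a month-scale
    mean hardly moves.
    """

    shifts: dict[str, float] = field(
        default_factory=lambda: {
            "psychosis": 0.15,
            "phq9": 0.15,
            "gad7": 0.15,
            "sociability": -0.15,
            "sleep_survey": -0.15,
            "medication": -0.2,  # partial non-adherence precedes relapse
            "sleep_duration": -0.75,
            "home_time": 0.75,
            "screen_duration": 0.75,
        }
    )
    window_days: int = 14
    variance_inflation: float = 1.5
    spike_rate: float = 0.2
    spike_feature_prob: float = 0.5
    spike_scale: float = 4.0
    #: probability an acute excursion points in the deterioration
    #: direction; near-symmetric by default because self-report during a
    #: crisis is unreliable (poor insight), so sharp excursions swing
    #: both ways and largely cancel in a monthly mean
    spike_directional_prob: float = 0.55

    def validate(self) -> None:
        if self.window_days < 0:
            raise ConfigError("relapse_effect.window_days must be >= 0")
        if self.variance_inflation <= 0:
            raise ConfigError("relapse_effect.variance_inflation must be > 0")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ConfigError("relapse_effect.spike_rate must lie in [0, 1]")
        if not 0.0 <= self.spike_feature_prob <= 1.0:
            raise ConfigError("relapse_effect.spike_feature_prob must lie in [0, 1]")
        if not 0.0 <= self.spike_directional_prob <= 1.0:
            raise ConfigError(
                "relapse_effect.spike_directional_prob must lie in [0, 1]"
            )
        if self.spike_scale < 0:
            raise ConfigError("relapse_effect.spike_scale must be >= 0")
        for f in self.shifts:
            if f not in ALL_FEATURES:
                raise ConfigError(f"relapse_effect.shifts: unknown feature {f!r}")


def _default_site_specs() -> dict[str, dict[str, int]]:
    # default composition: 33 / 49 / 50 participants, R = 9 / 8 / 3
    return {
        "Boston": {"R": 9, "NR": 17, "C": 7},
        "Bangalore": {"R": 8, "NR": 17, "C": 24},
        "Bhopal": {"R": 3, "NR": 22, "C": 25},
    }


@dataclass
class CohortConfig:
    site_specs: dict[str, dict[str, int]] = field(default_factory=_default_site_specs)
    enrollment_mean_days: float = 156.0
    enrollment_sd_days: float = 65.0
    min_enrollment_days: int = 30
    active_quality_target: float = 0.285
    passive_quality_target: float = 0.574
    stream_specs: dict[str, StreamSpec] = field(
        default_factory=lambda: dict(DEFAULT_STREAM_SPECS)
    )
    relapse_effect: RelapseEffect = field(default_factory=RelapseEffect)
    relapses_per_R: int = 1
    #: SD of stable per-participant baseline offsets, as a fraction of
    #: each stream's within-person SD (between-person heterogeneity)
    between_participant_sd: float = 0.8
    #: mean spacing of sub-threshold symptom exacerbations in SZ
    #: participants (transient bad patches that never meet a relapse
    #: criterion); 0 disables them
    minor_episode_every_days: float = 75.0
    #: per-episode strength drawn uniformly from this range: sustained
    #: shifts scale with strength (full-magnitude non-adherence without
    #: relapse does happen)
    minor_episode_strength_range: tuple[float, float] = (0.4, 1.2)
    #: extra damping of the acute spike component during episodes — a
    #: sudden escalation requiring intervention would, by definition,
    #: be a relapse, so episodes are mostly spike-free
    minor_episode_spike_factor: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for site, spec in self.site_specs.items():
            for grp, n in spec.items():
                if grp not in GROUPS:
                    raise ConfigError(f"site_specs[{site}]: unknown group {grp!r}")
                if not (isinstance(n, (int, np.integer)) and n >= 0):
                    raise ConfigError(f"site_specs[{site}][{grp}] must be a count >= 0")
        if self.enrollment_sd_days < 0:
            raise ConfigError("enrollment_sd_days must be >= 0")
        if self.min_enrollment_days < 1:
            raise ConfigError("min_enrollment_days must be >= 1")
        for name, target in (
            ("active_quality_target", self.active_quality_target),
            ("passive_quality_target", self.passive_quality_target),
        ):
            if not 0.0 <= target <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name, spec in self.stream_specs.items():
            spec.validate(name)
        self.relapse_effect.validate()
        if self.relapses_per_R < 0:
            raise ConfigError("relapses_per_R must be >= 0")
        if self.between_participant_sd < 0:
            raise ConfigError("between_participant_sd must be >= 0")
        if self.minor_episode_every_days < 0:
            raise ConfigError("minor_episode_every_days must be >= 0")
        lo, hi = self.minor_episode_strength_range
        if not 0 <= lo <= hi:
            raise ConfigError("minor_episode_strength_range must satisfy 0 <= lo <= hi")
        if self.minor_episode_spike_factor < 0:
            raise ConfigError("minor_episode_spike_factor must be >= 0")


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Read a :class:`CohortConfig` from a YAML or JSON file."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if "stream_specs" in raw:
        raw["stream_specs"] = {k: StreamSpec(**v) for k, v in raw["stream_specs"].items()}
    if "relapse_effect" in raw:
        raw["relapse_effect"] = RelapseEffect(**raw["relapse_effect"])
    cfg = CohortConfig(**raw)
    cfg.validate()
    return cfg


@dataclass
class DailyFeatureMatrix:
    """Per-participant day x feature values; NaN marks a missing value.

    Day indices are a gap-free 0..n-1 range: rows are never missing,
    individual values may be.
    """

    participant_id: str
    data: pd.DataFrame  # index: day, columns: ALL_FEATURES

    @property
    def n_days(self) -> int:
        return len(self.data)

    def channel(self, channel: str) -> pd.DataFrame:
        return self.data[list(CHANNEL_FEATURES[channel])]

    def copy(self) -> "DailyFeatureMatrix":
        return DailyFeatureMatrix(self.participant_id, self.data.copy())


@dataclass
class Cohort:
    participants: pd.DataFrame  # id, site, group, age, sex, education, enrollment_days
    relapses: pd.DataFrame      # id, day, criterion
    monthly: pd.DataFrame       # id, visit, instrument, score
    config: CohortConfig
    seed: int
    #: sub-threshold exacerbations (id, day, strength); carry a scaled
    #: signature but no relapse label
    episodes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["id", "day", "strength"])
    )


# demographic marginals per site (age mean/sd; sex and education probabilities)
_AGE = {"Boston": (37.8, 10.4), "Bangalore": (30.8, 5.8), "Bhopal": (35.3, 14.7)}
_SEX_P = {
    "Boston": ((0.636, 0.303, 0.061), ("Female", "Male", "Other")),
    "Bangalore": ((0.347, 0.653, 0.0), ("Female", "Male", "Other")),
    "Bhopal": ((0.40, 0.60, 0.0), ("Female", "Male", "Other")),
}
EDUCATION_LEVELS = (
    "eighth_grade_or_less",
    "some_high_school",
    "high_school_grad",
    "some_college",
    "college_grad_or_higher",
)
_EDU_P = {
    "Boston": (0.0, 0.0, 0.09, 0.56, 0.35),
    "Bangalore": (0.0, 0.08, 0.25, 0.08, 0.59),
    "Bhopal": (0.12, 0.08, 0.10, 0.52, 0.18),
}
# relapse criterion mix: hospitalization 5, suicidality 2, panss 4, escalation 9 of 20
_CRITERION_P = {
    "panss_25pct": 0.20,
    "hospitalization": 0.25,
    "suicidality": 0.10,
    "symptom_escalation": 0.45,
}


def _truncnorm(mean: float, sd: float, lo: float, rng: np.random.Generator, size: int):
    if sd == 0:
        return np.full(size, max(mean, lo))
    a = (lo - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def truncated_normal_mean(mean: float, sd: float, lo: float) -> float:
    """Closed-form mean of a normal truncated below at ``lo``."""
    if sd == 0:
        return max(mean, lo)
    a = (lo - mean) / sd
    return mean + sd * stats.norm.pdf(a) / stats.norm.sf(a)


def generate_cohort(config: CohortConfig, seed: int | None = None) -> Cohort:
    """Draw participants, relapse events, and monthly assessments.

    Daily feature matrices are simulated separately (they are the
    expensive part) by :func:`simulate_cohort_features` or
    :func:`simulate_participant_days`. Deterministic given ``seed``.
    """
    config.validate()
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    rows = []
    pid = 0
    for site in sorted(config.site_specs):
        spec = config.site_specs[site]
        for grp in GROUPS:
            for _ in range(int(spec.get(grp, 0))):
                pid += 1
                rows.append({"id": f"P{pid:03d}", "site": site, "group": grp})
    participants = pd.DataFrame(rows, columns=["id", "site", "group"])
    n = len(participants)

    if n == 0:
        empty_rel = pd.DataFrame(columns=["id", "day", "criterion"])
        empty_mon = pd.DataFrame(columns=["id", "visit", "instrument", "score"])
        participants = participants.reindex(
            columns=["id", "site", "group", "age", "sex", "education", "enrollment_days"]
        )
        return Cohort(participants, empty_rel, empty_mon, config, seed)

    enroll = _truncnorm(
        config.enrollment_mean_days,
        config.enrollment_sd_days,
        config.min_enrollment_days,
        rng,
        n,
    )
    participants["enrollment_days"] = np.maximum(
        np.round(enroll).astype(int), config.min_enrollment_days
    )

    ages, sexes, edus = [], [], []
    for site in participants["site"]:
        m, s = _AGE.get(site, (33.0, 9.0))
        ages.append(float(np.clip(rng.normal(m, s), 18, 70)))
        p, labels = _SEX_P.get(site, ((0.5, 0.5, 0.0), ("Female", "Male", "Other")))
        sexes.append(labels[rng.choice(3, p=np.asarray(p) / np.sum(p))])
        ep = np.asarray(_EDU_P.get(site, (0.2,) * 5), dtype=float)
        edus.append(EDUCATION_LEVELS[rng.choice(5, p=ep / ep.sum())])
    participants["age"] = np.round(ages, 1)
    participants["sex"] = sexes
    participants["education"] = edus
    participants = participants[
        ["id", "site", "group", "age", "sex", "education", "enrollment_days"]
    ]

    # relapse events: R participants only, days uniform in [30, enrollment-1]
    crit_names = list(RELAPSE_CRITERIA)
    crit_p = np.array([_CRITERION_P[c] for c in crit_names])
    rel_rows = []
    for _, row in participants.iterrows():
        if row["group"] != "R":
            continue
        lo = min(30, row["enrollment_days"] - 1)
        days = rng.integers(lo, row["enrollment_days"], size=config.relapses_per_R)
        for d in sorted(set(int(x) for x in days)):
            rel_rows.append(
                {
                    "id": row["id"],
                    "day": d,
                    "criterion": crit_names[rng.choice(len(crit_names), p=crit_p)],
                }
            )
    relapses = pd.DataFrame(rel_rows, columns=["id", "day", "criterion"])

    # sub-threshold exacerbations: Poisson-many per SZ participant
    ep_rows = []
    lo_s, hi_s = config.minor_episode_strength_range
    if config.minor_episode_every_days > 0 and hi_s > 0:
        for _, row in participants.iterrows():
            if row["group"] not in ("R", "NR"):
                continue
            lam = row["enrollment_days"] / config.minor_episode_every_days
            for _ in range(int(rng.poisson(lam))):
                ep_rows.append(
                    {"id": row["id"],
                     "day": int(rng.integers(0, row["enrollment_days"])),
                     "strength": round(float(rng.uniform(lo_s, hi_s)), 3)}
                )
    episodes = pd.DataFrame(ep_rows, columns=["id", "day", "strength"])

    monthly = _simulate_monthly(participants, relapses, rng)
    return Cohort(participants, relapses, monthly, config, seed, episodes)


_MONTHLY_BASE = {
    # (SZ mean, control mean, sd, lo, hi)
    "PANSS": (65.0, 38.0, 10.0, PANSS_MIN, PANSS_MAX),
    "PHQ-9": (9.0, 3.0, 3.0, 0, 27),
    "GAD-7": (7.0, 2.5, 2.5, 0, 21),
    "SF-36": (55.0, 80.0, 10.0, 0, 100),
    "SFS": (100.0, 120.0, 12.0, 55, 171),
    "PSQI": (8.0, 4.0, 2.5, 0, 21),
    "WSS": (20.0, 10.0, 5.0, 0, 55),
    "BASIS-24": (1.5, 0.5, 0.5, 0, 4),
}


def _simulate_monthly(
    participants: pd.DataFrame, relapses: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    rel_by_id = relapses.groupby("id")["day"].apply(list) if len(relapses) else {}
    for _, p in participants.iterrows():
        visits = range(int(p["enrollment_days"]) // 30 + 1)
        is_sz = p["group"] in ("R", "NR")
        for inst in MONTHLY_INSTRUMENTS:
            mu_sz, mu_c, sd, lo, hi = _MONTHLY_BASE[inst]
            base = rng.normal(mu_sz if is_sz else mu_c, sd)
            prev = None
            for v in visits:
                score = float(np.clip(base + rng.normal(0, sd / 2), lo, hi))
                if inst == "PANSS" and p["id"] in rel_by_id:
                    for rd in rel_by_id[p["id"]]:
                        if v == int(np.ceil(rd / 30)) and prev is not None:
                            score = float(min(prev * 1.25 * 1.02, PANSS_MAX))
                rows.append(
                    {"id": p["id"], "visit": v, "instrument": inst,
                     "score": round(score, 1)}
                )
                prev = score
    return pd.DataFrame(rows, columns=["id", "visit", "instrument", "score"])


def simulate_participant_days(
    participant: pd.Series | dict,
    config: CohortConfig,
    rng: np.random.Generator,
) -> DailyFeatureMatrix:
    """Simulate one participant's daily matrix.

    Each configured stream follows a stationary AR(1) around its
    baseline; each active value is independently missing with
    probability ``1 - active_quality_target`` and each passive value
    with ``1 - passive_quality_target``. Quality-channel features are
    computed completeness ratios, never sampled.
    """
    n = int(participant["enrollment_days"])
    if n < 1:
        raise ValueError("enrollment_days must be >= 1")
    data = {}
    for name in ACTIVE_FEATURES + PASSIVE_FEATURES:
        spec = config.stream_specs[name]
        # stable person-level baseline offset (between-person heterogeneity)
        center = spec.mean + rng.normal(0.0, config.between_participant_sd * spec.sd)
        innov = rng.normal(0.0, spec.sd * np.sqrt(1 - spec.phi**2), size=n)
        x = np.empty(n)
        x[0] = rng.normal(center, spec.sd)
        for t in range(1, n):
            x[t] = center + spec.phi * (x[t - 1] - center) + innov[t]
        q = (
            config.active_quality_target
            if FEATURE_CHANNEL[name] == "active"
            else config.passive_quality_target
        )
        x[rng.random(n) >= q] = np.nan
        data[name] = x
    df = pd.DataFrame(data, index=pd.RangeIndex(n, name="day"))
    df["active_quality"] = df[list(ACTIVE_FEATURES)].notna().mean(axis=1)
    df["passive_quality"] = df[list(PASSIVE_FEATURES)].notna().mean(axis=1)
    return DailyFeatureMatrix(str(participant["id"]), df[list(ALL_FEATURES)])


def inject_relapse_signature(
    matrix: DailyFeatureMatrix,
    event: pd.Series | dict,
    effect: RelapseEffect,
    stream_specs: dict[str, StreamSpec] | None = None,
    monthly: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> DailyFeatureMatrix:
    """Apply the relapse signature inside the effect window.

    Sustained part: within-window values are rescaled about the window
    mean by ``sqrt(variance_inflation)`` (deterministic), then shifted
    by delta*SD. Acute part: spike days drawn with ``spike_rate`` add
    sign-symmetric ``spike_scale``*SD excursions to a random subset of
    the shifted features; the spike RNG is derived from the participant
    id and event day when not supplied, so injection stays reproducible.
    Cells outside the window, and missing cells, are unchanged. If
    ``monthly`` is given, the PANSS score at the visit containing the
    event day is raised to at least 125% of the previous visit's value
    (in place).
    """
    specs = stream_specs or DEFAULT_STREAM_SPECS
    day = int(event["day"])
    n = matrix.n_days
    if not 0 <= day < n:
        raise IndexError(f"relapse day {day} outside enrollment [0, {n})")
    if rng is None:
        tag = zlib.crc32(f"{event['id']}:{day}".encode())
        rng = np.random.default_rng(np.random.SeedSequence([tag, 0x51DE]))
    out = matrix.copy()
    lo, hi = max(0, day - effect.window_days), min(n - 1, day + effect.window_days)
    window = slice(lo, hi)  # .loc slice: inclusive of hi
    shifted = list(effect.shifts)
    spike_days = (
        rng.random(hi - lo + 1) < effect.spike_rate
        if effect.spike_rate > 0
        else np.zeros(hi - lo + 1, dtype=bool)
    )
    spike_mask = rng.random((hi - lo + 1, len(shifted))) < effect.spike_feature_prob
    directional = (
        rng.random((hi - lo + 1, len(shifted))) < effect.spike_directional_prob
    )
    for j, (feat, delta) in enumerate(effect.shifts.items()):
        col = out.data[feat]
        seg = col.loc[window]
        if effect.variance_inflation != 1.0 and seg.notna().sum() > 1:
            mu = seg.mean()
            seg = mu + np.sqrt(effect.variance_inflation) * (seg - mu)
        seg = seg + delta * specs[feat].sd
        if effect.spike_scale > 0:
            base_sign = np.sign(delta) if delta != 0 else 1.0
            sign = np.where(directional[:, j], base_sign, -base_sign)
            spikes = (
                (spike_days & spike_mask[:, j])
                * sign
                * effect.spike_scale
                * specs[feat].sd
            )
            seg = seg + spikes
        out.data.loc[window, feat] = seg

    if monthly is not None:
        pid = str(event["id"])
        visit = int(np.ceil(day / 30))
        mask = (monthly["id"] == pid) & (monthly["instrument"] == "PANSS")
        panss = monthly.loc[mask].sort_values("visit")
        prev = panss.loc[panss["visit"] < visit, "score"]
        here = panss.loc[panss["visit"] == visit]
        if len(prev) and len(here):
            target = min(float(prev.iloc[-1]) * 1.25, PANSS_MAX)
            if float(here["score"].iloc[0]) < target:
                monthly.loc[here.index, "score"] = round(target, 1)
    return out


def scaled_effect(
    effect: RelapseEffect, strength: float, spike_factor: float = 1.0
) -> RelapseEffect:
    """A sub-threshold version of the signature.

    Sustained shifts and variance inflation scale with ``strength``;
    the acute spike rate additionally scales with ``spike_factor``
    (episodes are mostly spike-free — a sudden escalation requiring
    intervention would be a relapse)."""
    return RelapseEffect(
        shifts={k: v * strength for k, v in effect.shifts.items()},
        window_days=effect.window_days,
        variance_inflation=1.0 + (effect.variance_inflation - 1.0) * strength,
        spike_rate=effect.spike_rate * strength * spike_factor,
        spike_feature_prob=effect.spike_feature_prob,
        spike_scale=effect.spike_scale,
        spike_directional_prob=effect.spike_directional_prob,
    )


def simulate_cohort_features(
    cohort: Cohort, config: CohortConfig | None = None
) -> dict[str, DailyFeatureMatrix]:
    """Daily matrices for every participant, with relapse signatures
    injected for R participants and scaled sub-threshold episode
    signatures for SZ participants carrying episodes.

    Child RNGs are derived per participant from the cohort seed, so the
    result is reproducible regardless of evaluation order.
    """
    config = config or cohort.config
    matrices: dict[str, DailyFeatureMatrix] = {}
    rel_by_id = (
        cohort.relapses.groupby("id") if len(cohort.relapses) else None
    )
    ep_by_id = (
        cohort.episodes.groupby("id") if len(cohort.episodes) else None
    )
    for i, (_, p) in enumerate(cohort.participants.iterrows()):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(cohort.seed), 0xDA7A, i])
        )
        m = simulate_participant_days(p, config, rng)
        if rel_by_id is not None and p["id"] in rel_by_id.groups:
            for _, ev in rel_by_id.get_group(p["id"]).iterrows():
                m = inject_relapse_signature(
                    m, ev, config.relapse_effect, config.stream_specs,
                    monthly=cohort.monthly,
                )
        if ep_by_id is not None and p["id"] in ep_by_id.groups:
            for _, ev in ep_by_id.get_group(p["id"]).iterrows():
                minor = scaled_effect(
                    config.relapse_effect,
                    float(ev.get("strength", 1.0)),
                    config.minor_episode_spike_factor,
                )
                m = inject_relapse_signature(m, ev, minor, config.stream_specs)
        matrices[p["id"]] = m
    return matrices


# ---------------------------------------------------------------------------
# delimited-file interface


def write_cohort(
    cohort: Cohort,
    outdir: str | Path,
    matrices: dict[str, DailyFeatureMatrix] | None = None,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["participants"] = outdir / "participants.csv"
    cohort.participants.to_csv(paths["participants"], index=False)
    paths["relapses"] = outdir / "relapses.csv"
    cohort.relapses.to_csv(paths["relapses"], index=False)
    paths["monthly"] = outdir / "monthly.csv"
    cohort.monthly.to_csv(paths["monthly"], index=False)
    paths["episodes"] = outdir / "episodes.csv"
    cohort.episodes.to_csv(paths["episodes"], index=False)
    if matrices is not None:
        paths["features"] = outdir / "features.csv"
        features_frame(matrices).to_csv(paths["features"], index=False)
    return paths


def features_frame(matrices: dict[str, DailyFeatureMatrix]) -> pd.DataFrame:
    """Long-form (id, day, channel, feature, value) table; NaN = missing."""
    frames = []
    for pid, m in matrices.items():
        long = m.data.reset_index().melt(
            id_vars="day", var_name="feature", value_name="value"
        )
        long.insert(0, "id", pid)
        long["channel"] = long["feature"].map(FEATURE_CHANNEL)
        frames.append(long[["id", "day", "channel", "feature", "value"]])
    if not frames:
        return pd.DataFrame(columns=["id", "day", "channel", "feature", "value"])
    return pd.concat(frames, ignore_index=True).sort_values(
        ["id", "day", "feature"], kind="stable", ignore_index=True
    )


def matrices_from_frame(features: pd.DataFrame) -> dict[str, DailyFeatureMatrix]:
    out = {}
    for pid, grp in features.groupby("id"):
        wide = grp.pivot_table(
            index="day", columns="feature", values="value", aggfunc="first",
            dropna=False,
        )
        n = int(wide.index.max()) + 1 if len(wide) else 0
        wide = wide.reindex(index=pd.RangeIndex(n, name="day"))
        wide = wide.reindex(columns=[f for f in ALL_FEATURES if f in wide.columns])
        out[str(pid)] = DailyFeatureMatrix(str(pid), wide)
    return out


def read_cohort(indir: str | Path, config: CohortConfig | None = None) -> tuple:
    """Read (cohort, matrices) from the delimited-file layout."""
    indir = Path(indir)
    for name in ("participants.csv", "relapses.csv", "monthly.csv", "features.csv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing input file: {indir / name}")
    participants = pd.read_csv(indir / "participants.csv")
    relapses = pd.read_csv(indir / "relapses.csv")
    monthly = pd.read_csv(indir / "monthly.csv")
    matrices = matrices_from_frame(pd.read_csv(indir / "features.csv"))
    ep_path = indir / "episodes.csv"
    episodes = (
        pd.read_csv(ep_path)
        if ep_path.exists()
        else pd.DataFrame(columns=["id", "day", "strength"])
    )
    cohort = Cohort(
        participants, relapses, monthly, config or CohortConfig(), -1, episodes
    )
    return cohort, matrices
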