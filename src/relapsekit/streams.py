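"""Feature registry: channels, clinical feature groups, and instrument lists.

Every daily feature belongs to exactly one collection channel (active
surveys, passive sensors, or data-quality ratios) and to exactly one
clinical feature group used when attributing anomalies.
"""

from __future__ import annotations

SITES = ("Boston", "Bangalore", "Bhopal")
GROUPS = ("R", "NR", "C")  # relapsed / non-relapsed schizophrenia / control

#: daily active features: one score per in-app survey instrument
ACTIVE_FEATURES = (
    "phq9",
    "gad7",
    "psychosis",
    "sociability",
    "sleep_survey",
    "medication",
)

#: daily passive features derived from GPS / accelerometer / screen state
PASSIVE_FEATURES = ("sleep_duration", "home_time", "screen_duration")

#: daily completeness ratios, themselves monitored as a signal
QUALITY_FEATURES = ("active_quality", "passive_quality")

ALL_FEATURES = ACTIVE_FEATURES + PASSIVE_FEATURES + QUALITY_FEATURES

CHANNELS = ("active", "passive", "quality")

FEATURE_CHANNEL = {
    **{f: "active" for f in ACTIVE_FEATURES},
    **{f: "passive" for f in PASSIVE_FEATURES},
    **{f: "quality" for f in QUALITY_FEATURES},
}

CHANNEL_FEATURES = {
    ch: tuple(f for f in ALL_FEATURES if FEATURE_CHANNEL[f] == ch)
    for ch in CHANNELS
}

#: clinical feature groups, in their canonical (tie-breaking) order
GROUP_ORDER = (
    "symptoms",
    "sociability",
    "medication",
    "sleep",
    "hometime_screen",
    "engagement",
)

FEATURE_GROUP = {
    "phq9": "symptoms",
    "gad7": "symptoms",
    "psychosis": "symptoms",
    "sociability": "sociability",
    "medication": "medication",
    "sleep_survey": "sleep",
    "sleep_duration": "sleep",
    "home_time": "hometime_screen",
    "screen_duration": "hometime_screen",
    "active_quality": "engagement",
    "passive_quality": "engagement",
}

GROUP_FEATURES = {
    g: tuple(f for f in ALL_FEATURES if FEATURE_GROUP[f] == g)
    for g in GROUP_ORDER
}

#: monthly clinician/self-report instruments
MONTHLY_INSTRUMENTS = (
    "PANSS",
    "PHQ-9",
    "GAD-7",
    "SF-36",
    "SFS",
    "PSQI",
    "WSS",
    "BASIS-24",
)

PANSS_MIN, PANSS_MAX = 30, 210

RELAPSE_CRITERIA = (
    "panss_25pct",
    "hospitalization",
    "suicidality",
    "symptom_escalation",
)
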