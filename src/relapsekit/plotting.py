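"""Per-participant anomaly plots.

x = days since first data point; y = -log(p); one point color per
channel; solid vertical lines at relapse days; dashed horizontal line
at the anomaly cutoff.
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .anomaly import AnomalySeries

log = logging.getLogger(__name__)

CHANNEL_COLORS = {"active": "tab:blue", "passive": "tab:red", "quality": "tab:green"}


def plot_participant(
    series: dict[str, AnomalySeries],
    relapse_days: list[int],
    path: str | Path,
    alpha: float = 0.005,
) -> Path | None:
    """Write one participant's anomaly plot; returns the path, or None
    when there is nothing to plot."""
    if not any(len(s.table) for s in series.values()):
        log.info("no p-values to plot for %s", path)
        return None
    fig, ax = plt.subplots(figsize=(9, 3.2))
    for ch, s in series.items():
        if not len(s.table):
            continue
        ax.scatter(
            s.table.index,
            -np.log(s.table["p"]),
            s=8,
            color=CHANNEL_COLORS.get(ch, "gray"),
            label=ch,
        )
    for d in relapse_days:
        ax.axvline(d, color="black", lw=1.2)
    ax.axhline(-np.log(alpha), color="gray", ls="--", lw=1)
    ax.set_xlabel("days since first data point")
    ax.set_ylabel(r"$-\log(p)$")
    ax.legend(loc="upper right", fontsize=7)
    pid = next(iter(series.values())).participant_id
    ax.set_title(f"participant {pid}")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_correlation_heatmap(corr: "object", path: str | Path) -> Path:
    """Stream x instrument heatmap of changepoint-survey correlation p-values."""
    mat = corr.pivot(index="stream", columns="instrument", values="p")
    fig, ax = plt.subplots(figsize=(7, 2.6))
    im = ax.imshow(mat.to_numpy(dtype=float), cmap="viridis_r", vmin=0, vmax=1,
                   aspect="auto")
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=45, ha="right",
                  fontsize=7)
    ax.set_yticks(range(mat.shape[0]), mat.index, fontsize=8)
    fig.colorbar(im, label="p")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
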