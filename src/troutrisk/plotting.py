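"""Plotting helpers: per-species score-distribution boxplots."""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .uncertainty import MCResult, summarize_mc

__all__ = ["render_boxplot"]


def render_boxplot(
    result: MCResult,
    path: str | Path,
    threat_ordinals: Mapping[str, int] | None = None,
    display_names: Mapping[str, str] | None = None,
) -> Path:
    """Boxplots of simulated per-species totals, ordered by descending median.

    Optionally overlays each species' threat-status ordinal as a dot on a
    secondary axis.  If ``threat_ordinals`` misses species, the overlay is
    drawn for the species it covers and a warning is logged.
    """
    order = summarize_mc(result)["species"].tolist()
    idx = {sp: i for i, sp in enumerate(result.species)}
    data = [result.score_matrix[:, idx[sp]] for sp in order]
    labels = [display_names.get(sp, sp) if display_names else sp for sp in order]

    fig, ax = plt.subplots(figsize=(max(8, 0.3 * len(order)), 5))
    ax.boxplot(data, tick_labels=labels, showfliers=False)
    ax.set_ylabel("Weighted risk score")
    ax.set_xlabel("Species (ordered by median simulated score)")
    plt.setp(ax.get_xticklabels(), rotation=90, fontsize=7)

    if threat_ordinals is not None:
        covered = [sp for sp in order if sp in threat_ordinals]
        if len(covered) < len(order):
            warnings.warn(
                f"threat overlay missing {len(order) - len(covered)} species",
                stacklevel=2,
            )
        if covered:
            ax2 = ax.twinx()
            xs = [order.index(sp) + 1 for sp in covered]
            ys = [threat_ordinals[sp] for sp in covered]
            ax2.plot(xs, ys, "ro", ms=4, zorder=5)
            ax2.set_ylabel("Threat-status ordinal", color="r")
            ax2.set_ylim(0, max(ys) + 1)

    med = [float(np.median(d)) for d in data]
    ax.set_ylim(min(7, min(map(min, data))) - 1, max(31, max(med) + 1))
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
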