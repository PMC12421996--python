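"""Non-normative figures: distance trace with the kissing threshold line and
dual-axis intensity series."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .kissing import DistanceTrace


def plot_distance_trace(
    trace: DistanceTrace,
    threshold_um: float = 0.25,
    path: Optional[str | Path] = None,
):
    """Distance trace with the co-localization threshold as a red line."""
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace.time_s, trace.distance_um, lw=1, color="k")
    ax.axhline(threshold_um, color="red", lw=1, label=f"threshold {threshold_um} µm")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("centre distance (µm)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_intensity_series(
    trace: DistanceTrace, path: Optional[str | Path] = None
):
    """Dual-axis protein/RNA intensity series over time."""
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(trace.time_s, trace.gag_intensity, color="tab:red", lw=1, label="Gag")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("Gag intensity (A.U.)", color="tab:red")
    ax2 = ax.twinx()
    ax2.plot(trace.time_s, trace.rna_intensity, color="tab:green", lw=1, label="USvRNA")
    ax2.set_ylabel("USvRNA intensity (A.U.)", color="tab:green")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
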