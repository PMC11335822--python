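"""Stimulus-space rendering of a representative scanpath with its AOIs."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .aggregation import RepresentativeScanpath
from .model import ScanpathSample

__all__ = ["plot_representative"]


def plot_representative(
    sample: ScanpathSample, rep: RepresentativeScanpath, path: str | Path
) -> None:
    """Draw sample scanpaths (thin), AOI polygons, and the representative
    scanpath (thick) with circle areas proportional to AOI duration."""
    fig, ax = plt.subplots(figsize=(8, 6))
    stim = sample.stimulus
    for sp in sample:
        pos = sp.positions
        ax.plot(pos[:, 0], pos[:, 1], "-o", ms=2, lw=0.6, alpha=0.4)
    max_dur = max(a.duration for a in rep.aois)
    for j, aoi in enumerate(rep.aois):
        for comp in aoi.region.components:
            xs, ys = comp.exterior.xy
            ax.fill(xs, ys, alpha=0.25, color="tab:red", lw=1.0, ec="tab:red")
        cx, cy = aoi.center
        ax.scatter([cx], [cy], s=40 + 400 * aoi.duration / max_dur,
                   color="tab:red", zorder=5, alpha=0.8)
        ax.annotate(str(j + 1), (cx, cy), color="white", ha="center",
                    va="center", zorder=6, fontsize=8)
    pos = rep.scanpath.positions
    ax.plot(pos[:, 0], pos[:, 1], "-", color="tab:red", lw=2.5, zorder=4)
    ax.set_xlim(0, stim.width)
    ax.set_ylim(stim.height, 0)  # screen coordinates: y grows downward
    ax.set_xlabel("x [px]")
    ax.set_ylabel("y [px]")
    ax.set_title(f"representative scanpath (theta={rep.theta_used})")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
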