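"""Track-panel plotting for reporter occupancy (16/21/28 nt RPF panels)."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .asite import OccupancyTrack

_CLASS_ORDER = ("16", "21", "28")


def plot_reporter_tracks(
    tracks: Mapping[str, OccupancyTrack],
    path: str | Path,
    stall_interval: tuple[int, int] | None = None,
    title: str = "",
    class_order: Sequence[str] = _CLASS_ORDER,
) -> None:
    """Stacked per-size-class occupancy panels with the stall insert shaded."""
    classes = [c for c in class_order if c in tracks] or sorted(tracks)
    fig, axes = plt.subplots(
        len(classes), 1, figsize=(8, 1.8 * len(classes)), sharex=True, squeeze=False
    )
    for ax, name in zip(axes[:, 0], classes):
        track = tracks[name]
        ax.fill_between(range(len(track.counts)), track.counts, step="mid", lw=0)
        ax.set_ylabel(f"{name} nt")
        if stall_interval is not None:
            ax.axvspan(*stall_interval, alpha=0.15, color="red", lw=0)
    axes[-1, 0].set_xlabel("transcript position (nt)")
    if title:
        axes[0, 0].set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
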