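"""Heatmaps of DSC / HD95 over the TR x TE grid, with the anchor marked."""

from __future__ import annotations

from pathlib import Path
from typing import List

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .relaxometry import AcquisitionParams  # noqa: E402

__all__ = ["plot_metric_heatmaps"]


def plot_metric_heatmaps(
    frame: pd.DataFrame,
    metric: str,
    anchor: AcquisitionParams,
    out_dir: str | Path,
    cmap: str = "viridis",
) -> List[Path]:
    """One heatmap per structure: TE on x, TR on y, missing (mixed) cells blank.

    The anchor acquisition is marked with a star (clipped into the plotted
    range when it lies outside the grid, as the default TE = 212 ms does).
    Returns the written PNG paths.
    """
    if metric not in ("dsc", "hd95_mm"):
        raise ValueError(f"unsupported metric {metric!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for structure, grp in frame.groupby("structure", sort=True):
        pivot = grp.pivot_table(index="tr_ms", columns="te_ms",
                                values=metric, aggfunc="mean")
        fig, ax = plt.subplots(figsize=(7, 5))
        trs = pivot.index.to_numpy(dtype=float)
        tes = pivot.columns.to_numpy(dtype=float)
        mesh = ax.pcolormesh(tes, trs, np.ma.masked_invalid(pivot.to_numpy()),
                             shading="nearest", cmap=cmap)
        fig.colorbar(mesh, ax=ax, label=metric)
        ax.plot(min(anchor.te, tes.max()), min(anchor.tr, trs.max()),
                marker="*", markersize=16, color="gold",
                markeredgecolor="black")
        ax.set_xlabel("TE (ms)")
        ax.set_ylabel("TR (ms)")
        ax.set_title(f"{structure}: {metric} across the TR x TE grid")
        path = out_dir / f"heatmap_{metric}_{structure}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
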