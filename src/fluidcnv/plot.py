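"""Optional copy-ratio scatter plot (gray bins, orange segment means)."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ratio import CopyRatioProfile

__all__ = ["plot_profile"]


def plot_profile(
    profile: CopyRatioProfile,
    bins: pd.DataFrame,
    segments: pd.DataFrame | None = None,
    path=None,
    ylim: tuple[float, float] = (-2.0, 2.0),
):
    """Genome-wide scatter of bin log2 ratios with segment mean overlays.

    Requires matplotlib; returns the figure (saved to ``path`` if given).
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chrom_names = list(bins["chromosome"].cat.categories)
    offsets: dict[str, int] = {}
    pos = 0
    for name in chrom_names:
        offsets[name] = pos
        pos += int(bins.loc[bins["chromosome"] == name, "end"].max())

    fig, ax = plt.subplots(figsize=(14, 3.5))
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2
    x = mid + bins["chromosome"].astype(str).map(offsets).to_numpy()
    ax.scatter(x, np.clip(profile.log2, *ylim), s=3, c="0.6", linewidths=0)
    if segments is not None:
        for _, seg in segments.iterrows():
            off = offsets[str(seg["chromosome"])]
            ax.plot(
                [off + seg["start"], off + seg["end"]],
                [seg["mean_log2"]] * 2,
                color="orange",
                lw=2,
            )
    for name in chrom_names[1:]:
        ax.axvline(offsets[name], color="0.85", lw=0.5)
    ax.axhline(0.0, color="0.3", lw=0.5, ls="--")
    ax.set_ylim(*ylim)
    ax.set_xlim(0, pos)
    ax.set_ylabel("log2 copy ratio")
    ax.set_title(profile.sample_id)
    ax.set_xticks([offsets[n] for n in chrom_names])
    ax.set_xticklabels([n.removeprefix("chr") for n in chrom_names], fontsize=6)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
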