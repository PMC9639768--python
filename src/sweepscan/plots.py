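"""Simple diagnostic plots: per-chromosome candidate-region tracks and
LD-decay curves. Matplotlib is imported lazily so headless pipelines that
never plot do not need a display backend configured."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def plot_ld_decay(profiles: dict[str, pd.DataFrame], path: str | Path) -> None:
    """Overlay mean-r^2 decay curves for several populations."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for pop, prof in profiles.items():
        mid = (prof["bin_start"] + prof["bin_end"]) / 2e3
        ax.plot(mid, prof["mean_r2"], marker="o", ms=3, label=pop)
    ax.set_xlabel("distance (kb)")
    ax.set_ylabel(r"mean $r^2$")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_region_track(
    regions: pd.DataFrame, chrom_lengths: dict[str, int], path: str | Path
) -> None:
    """One horizontal line per chromosome; colored ticks mark candidate
    regions, haplotype-scan sources above the line and the FST/diversity
    cross analysis below."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    colors = {"iHS": "tab:red", "xpEHH": "tab:orange", "xpFstPi": "tab:blue"}
    chroms = list(chrom_lengths)
    fig, ax = plt.subplots(figsize=(8, 0.8 * len(chroms) + 1))
    for y, chrom in enumerate(chroms):
        ax.hlines(y, 0, chrom_lengths[chrom] / 1e6, color="grey", lw=3, zorder=1)
        sub = regions[regions["chrom"] == chrom]
        for row in sub.itertuples():
            above = row.source in ("iHS", "xpEHH")
            y0, y1 = (y, y + 0.25) if above else (y - 0.25, y)
            ax.vlines(
                (row.start + row.end) / 2e6, y0, y1,
                color=colors.get(row.source, "k"), lw=2, zorder=2,
            )
    ax.set_yticks(range(len(chroms)), chroms)
    ax.set_xlabel("position (Mb)")
    handles = [plt.Line2D([], [], color=c, lw=2, label=s) for s, c in colors.items()]
    ax.legend(handles=handles, frameon=False, loc="upper right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
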