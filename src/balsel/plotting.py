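"""Minimal plotting helpers: per-gene tracks and category violins."""

from __future__ import annotations

__all__ = ["plot_gene_tracks", "plot_category_violin"]


def plot_gene_tracks(track, beta_track=None, threshold=None, ax=None):
    """Sliding-window pi / Tajima's D (and optional per-SNP beta_std) lines."""
    import matplotlib.pyplot as plt

    df = track.to_dataframe()
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    mid = (df["start"] + df["end"]) / 2
    ax.plot(mid, df["pi"], label="pi", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(mid, df["tajimaD"], label="Tajima's D", color="tab:orange")
    if beta_track is not None and len(beta_track):
        ax2.scatter(
            beta_track["pos"], beta_track["beta_std"], s=6, color="tab:green",
            label="beta_std",
        )
    if threshold is not None:
        ax2.axhline(threshold, ls="--", color="red", lw=0.8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("pi / site")
    ax2.set_ylabel("Tajima's D / beta_std")
    return ax


def plot_category_violin(values_by_category: dict, ax=None):
    """Violin plot of gene-level beta_std_max by gene category."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    labels = list(values_by_category)
    ax.violinplot([values_by_category[k] for k in labels], showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("beta_std_max")
    return ax
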