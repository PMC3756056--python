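"""Convenience plots: genome-scan Manhattan panels and probability heatmaps."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mapping import _chrom_sort_key


def manhattan(scan_table: pd.DataFrame, fdr_level: float = 0.05, ax=None):
    """-log10(p) against genome position, one color block per chromosome.

    ``scan_table`` is the frame produced by :func:`pamcross.mapping.genome_scan`.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    chroms = sorted(scan_table["chrom"].unique(), key=_chrom_sort_key)
    offset = 0.0
    ticks = []
    for i, c in enumerate(chroms):
        sub = scan_table[scan_table["chrom"] == c].sort_values("pos_mb")
        x = sub["pos_mb"].to_numpy() + offset
        ax.scatter(x, -np.log10(sub["p"]), s=6, color=f"C{i % 2}")
        ticks.append((offset + x[-1]) / 2 if len(x) else offset)
        offset = x[-1] + 5 if len(x) else offset
    sig = scan_table[scan_table["significant"]]
    if len(sig):
        thresh = -np.log10(sig["p"].max())
        ax.axhline(thresh, ls="--", color="grey", lw=1)
    ax.set_xticks(ticks)
    ax.set_xticklabels(chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax


def probability_heatmap(probs: pd.DataFrame, ax=None):
    """Query samples × subtype probability matrix as a heatmap."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, max(3, 0.1 * len(probs))))
    data = probs.to_numpy(dtype=float)
    im = ax.imshow(data, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(probs.shape[1]))
    ax.set_xticklabels(probs.columns, rotation=45, ha="right")
    ax.set_ylabel("query sample")
    ax.figure.colorbar(im, ax=ax, label="probability")
    return ax
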