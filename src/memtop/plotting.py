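"""Figure rendering: site-abundance bar plots with topology overlay, pair heat maps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .landscape import AMINO_ACIDS, SiteProfile
from .masses_ions import ProteinSpec

__all__ = ["plot_site_profile", "plot_pair_heatmap"]


def plot_site_profile(
    profile: SiteProfile,
    spec: ProteinSpec | None = None,
    ax: plt.Axes | None = None,
):
    """Bar plot of per-site abundance colored by weighted average charge.

    TM helices (yellow boxes) and loops (gray baseline) are overlaid when a
    topology-annotated spec is supplied.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3.5))
    sites = profile.sites
    charges = profile.weighted_avg_charge
    vmax = charges.max() if charges.max() > 0 else 1.0
    colors = plt.cm.viridis(charges / vmax)
    ax.bar(sites, profile.abundance, width=1.0, color=colors)
    if spec is not None:
        y0 = -8.0
        ax.axhline(0, color="0.6", lw=0.8)
        for seg in spec.tm_segments():
            ax.add_patch(
                plt.Rectangle(
                    (seg.start, y0), seg.end - seg.start, 6.0,
                    facecolor="gold", edgecolor="k", lw=0.4,
                )
            )
            ax.text(
                (seg.start + seg.end) / 2, y0 + 3, str(seg.helix_index),
                ha="center", va="center", fontsize=7,
            )
        ax.set_ylim(y0 - 2, max(105, profile.abundance.max() + 5))
    ax.set_xlabel("cleavage site (residue number)")
    ax.set_ylabel("relative abundance")
    return ax


def plot_pair_heatmap(H: np.ndarray, ax: plt.Axes | None = None):
    """Heat map of cleavage abundance by (N-terminal | C-terminal) residue pair."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    im = ax.imshow(H, cmap="magma", origin="upper")
    ax.set_xticks(range(20), list(AMINO_ACIDS), fontsize=7)
    ax.set_yticks(range(20), list(AMINO_ACIDS), fontsize=7)
    ax.set_xlabel("C-terminal residue")
    ax.set_ylabel("N-terminal residue")
    plt.colorbar(im, ax=ax, label="summed normalized abundance")
    return ax
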