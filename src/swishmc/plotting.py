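"""Figure helpers: per-residue helicity stacked bars and backbone
hydrogen-bond frequency heat maps."""

from __future__ import annotations

import numpy as np

from .ssa import HelicityProfile
from .interactions import HBondFrequencyMatrix


def helicity_stacked_bar(profile: HelicityProfile, sequence: str = "",
                         title: str = ""):
    """Stacked bar plot of per-residue alpha and 3-10 helix percentages."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    L = len(profile.h_fraction)
    x = np.arange(1, L + 1)
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * L), 3.2))
    ax.bar(x, 100 * profile.h_fraction, color="#4466bb", label=r"$\alpha$")
    ax.bar(x, 100 * profile.g_fraction, bottom=100 * profile.h_fraction,
           color="#cc8844", label=r"$3_{10}$")
    if sequence:
        ax.set_xticks(x)
        ax.set_xticklabels([f"{c}{i}" for i, c in enumerate(sequence, 1)],
                           rotation=90, fontsize=7)
    ax.set_xlabel("residue")
    ax.set_ylabel("helix %")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    return fig


def hbond_heatmap(matrix: HBondFrequencyMatrix, title: str = ""):
    """Heat map of CO(i) -> NH(i+k) bond frequencies (offsets as rows)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    vals = matrix.values
    fig, ax = plt.subplots(figsize=(max(6, 0.4 * vals.shape[1]), 2.4))
    im = ax.imshow(vals, aspect="auto", vmin=0, vmax=1, cmap="viridis")
    ax.set_yticks(range(4))
    ax.set_yticklabels([f"i+{k}" for k in range(1, 5)])
    ax.set_xticks(range(vals.shape[1]))
    ax.set_xticklabels(range(1, vals.shape[1] + 1), fontsize=7)
    ax.set_xlabel("carbonyl residue i")
    fig.colorbar(im, ax=ax, label="bond frequency")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
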