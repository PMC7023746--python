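"""Minimal profile plotting: a bar chart over a scheme's channels."""

from __future__ import annotations

import numpy as np

_CLASS_COLORS = {
    "C>A": "#03BCEE", "C>G": "#010101", "C>T": "#E32926",
    "T>A": "#CAC9C9", "T>C": "#A1CE63", "T>G": "#EBC5C4",
}


def plot_profile(profile, ax=None, title: str = ""):
    """Bar plot of a signature profile (96-bar style for SBS-96).

    Returns the matplotlib axes. Channels are drawn in scheme order;
    SBS channels are coloured by substitution class.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    labels = list(profile.scheme.labels)
    colors = None
    if "[" in labels[0]:
        colors = [
            _CLASS_COLORS.get(lab[lab.index("[") + 1 : lab.index("]")], "#888888")
            for lab in labels
        ]
    ax.bar(np.arange(len(labels)), profile.weights, color=colors, width=0.8)
    ax.set_xticks(np.arange(len(labels)))
    ax.set_xticklabels(labels, rotation=90, fontsize=4, family="monospace")
    ax.set_ylabel("fraction of mutations")
    if title:
        ax.set_title(title)
    ax.margins(x=0.005)
    return ax
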