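"""Plots: signature profiles in the standard 96-channel layout, recovery
curves, and exposure heatmaps."""

from __future__ import annotations

import numpy as np

from .catalogue import ExposureMatrix, SignatureMatrix
from .evaluate import PRFTable

__all__ = ["plot_signatures", "plot_prf_curve", "plot_exposures"]

# Conventional colours of the six substitution-type blocks.
_BLOCK_COLOURS = ("#03BCEE", "#010101", "#E32926", "#CAC9C9", "#A1CE63",
                  "#EBC6C4")
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def plot_signatures(signatures: SignatureMatrix, axes=None):
    """Bar plots of each signature over the 96 channels, one row per
    signature, coloured by substitution type. Returns the matplotlib figure."""
    import matplotlib.pyplot as plt

    k = signatures.k
    if axes is None:
        fig, axes = plt.subplots(k, 1, figsize=(12, 1.8 * k), sharex=True,
                                 squeeze=False)
        axes = axes[:, 0]
    else:
        fig = axes[0].figure
    colours = np.repeat(_BLOCK_COLOURS, 16)
    x = np.arange(96)
    for j, ax in enumerate(axes):
        ax.bar(x, signatures.profiles[:, j], color=colours, width=0.8)
        ax.set_ylabel(signatures.signature_ids[j], fontsize=8)
        ax.set_xlim(-1, 96)
    axes[-1].set_xticks(np.arange(8, 96, 16))
    axes[-1].set_xticklabels(_SUBSTITUTIONS)
    fig.suptitle("Signature profiles (96 SBS channels)")
    return fig


def plot_prf_curve(prf: PRFTable, ax=None):
    """Precision / sensitivity / F1 against the cosine threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for metric in ("precision", "sensitivity", "f1"):
        ax.plot(prf.table["threshold"], prf.table[metric],
                label=f"{metric} (AUC {prf.auc[metric]:.2f})")
    ax.set_xlabel("cosine-similarity threshold")
    ax.set_ylabel("score")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    return ax.figure


def plot_exposures(exposures: ExposureMatrix, ax=None, log: bool = True):
    """Heatmap of exposures (samples x signatures)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    Z = exposures.values
    data = np.log10(Z + 1.0) if log else Z
    im = ax.imshow(data, aspect="auto", interpolation="nearest",
                   cmap="viridis")
    ax.set_xticks(range(len(exposures.signature_ids)))
    ax.set_xticklabels(exposures.signature_ids, rotation=90, fontsize=7)
    ax.set_ylabel("samples")
    label = "log10(exposure + 1)" if log else "exposure"
    ax.figure.colorbar(im, ax=ax, label=label)
    return ax.figure
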