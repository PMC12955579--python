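"""Minimal plotting helpers: interpolated scalp topography, wPLI heat map."""

from __future__ import annotations

import numpy as np

from .montage import ChannelLayout


def plot_topomap(values, layout: ChannelLayout | None = None, ax=None, **kwargs):
    """Interpolated scalp map of one value per non-EOG channel."""
    import matplotlib.pyplot as plt
    import mne

    layout = layout or ChannelLayout()
    labels = list(layout.non_eog_labels)
    values = np.asarray(values, dtype=float)
    if values.size != len(labels):
        raise ValueError(f"expected {len(labels)} values, got {values.size}")
    info = mne.create_info(labels, sfreq=500.0, ch_types="eeg")
    try:
        montage = mne.channels.make_standard_montage("colin27_1020")
    except ValueError:  # older MNE
        montage = mne.channels.make_standard_montage("standard_1020")
    info.set_montage(montage)
    if ax is None:
        _, ax = plt.subplots()
    mne.viz.plot_topomap(values, info, axes=ax, show=False, **kwargs)
    return ax


def plot_connectivity_matrix(matrix, ax=None, cmap="viridis"):
    """Heat map of a (wPLI) connectivity matrix with channel tick labels."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix.values, cmap=cmap, vmin=0)
    ticks = range(len(matrix.channels))
    ax.set_xticks(ticks, matrix.channels, rotation=90, fontsize=6)
    ax.set_yticks(ticks, matrix.channels, fontsize=6)
    ax.set_title(f"wPLI {matrix.condition} {matrix.window_ms} ms")
    plt.colorbar(im, ax=ax)
    return ax
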