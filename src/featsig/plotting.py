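"""Minimal plotting helpers (matplotlib; nothing here is load-bearing)."""

from __future__ import annotations

import numpy as np

from . import channels as ch

_BLOCK_COLORS = ["#03bcee", "#010101", "#e32926", "#cac9c9", "#a1cf63", "#ecc6c5"]


def plot_signature(profile: np.ndarray, ax=None, title: str | None = None):
    """Bar plot of a 96-channel profile in canonical order, colored by block."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 2.5))
    colors = [_BLOCK_COLORS[i // 16] for i in range(ch.N_CHANNELS)]
    ax.bar(range(ch.N_CHANNELS), np.asarray(profile, dtype=float), color=colors)
    ax.set_xticks(range(0, ch.N_CHANNELS, 16))
    ax.set_xticklabels([f"{r}>{a}" for r, a in ch.SUBSTITUTIONS])
    ax.set_xlim(-1, ch.N_CHANNELS)
    if title:
        ax.set_title(title)
    return ax
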