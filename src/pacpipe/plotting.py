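"""Optional figure rendering (matplotlib)."""

from __future__ import annotations

import numpy as np


def plot_palette(palette, path, title: str = "") -> None:
    """Render a coupling palette (frequency x phase bin) to an image file.

    Color is the mean z-scored log-broadband per bin, symmetric about zero
    and scaled to the palette maximum.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scale = palette.scale or 1.0
    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(
        np.append(palette.centers - np.pi / len(palette.centers),
                  palette.centers[-1] + np.pi / len(palette.centers)),
        np.append(palette.frequencies, palette.frequencies[-1] + 1),
        palette.means, cmap="RdBu_r", vmin=-scale, vmax=scale,
        shading="flat")
    ax.set_xlabel("rhythm phase (rad)")
    ax.set_ylabel("rhythm frequency (Hz)")
    ax.set_title(title or f"coupling palette (max {scale:.2f})")
    fig.colorbar(mesh, ax=ax, label="mean log-broadband (z)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
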