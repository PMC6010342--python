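"""Metagene plotting: mean profile lines with shaded confidence bands."""

from __future__ import annotations

from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .metaprofile import ProfileCI


def metagene_ci_plot(
    bands: Mapping[str, ProfileCI],
    path,
    ylabel: str = "mean ChIP z-score",
    title: str | None = None,
) -> None:
    """Plot one or more profile bands (grey shading = confidence band)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, ci in bands.items():
        x = ci.offsets() + ci.bin_bp / 2
        (line,) = ax.plot(x, ci.mean, label=label)
        ax.fill_between(x, ci.lower, ci.upper, color="grey", alpha=0.35)
    ax.axvline(0, color="k", lw=0.5, ls=":")
    ax.set_xlabel("oriented offset from summit (bp)")
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
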