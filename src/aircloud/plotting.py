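"""Cloud pictures: scatter plots of (x, mu) drops.

A cloud picture overlays the assessed indicator cloud (blue) on the five
standard clouds, coloured by severity (green, yellow, orange, red, pink).
Concentrations are physical quantities, so the horizontal axis is clamped to
start at zero even when a wide cloud would sample negative drops.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cloud import CloudModel, forward_generate
from .grading import StandardCloudSet

__all__ = ["LEVEL_COLOURS", "render_cloud_picture"]

LEVEL_COLOURS = ("green", "gold", "orange", "red", "violet")


def render_cloud_picture(
    assessed: CloudModel,
    standards: StandardCloudSet | Sequence[CloudModel],
    indicator: str,
    path: str | Path,
    n_drops: int = 1000,
    seed: int = 0,
    title: str | None = None,
) -> Path:
    """Render the assessed cloud against its standard clouds and save.

    Returns the written path.  Drop generation is seeded; each cloud gets an
    independent substream so the picture is reproducible.
    """
    if n_drops < 1:
        raise ValueError(f"n_drops must be >= 1, got {n_drops}")
    if isinstance(standards, StandardCloudSet):
        level_clouds = standards.level_clouds(indicator)
        labels = standards.levels
    else:
        level_clouds = tuple(standards)
        labels = tuple(f"level {i + 1}" for i in range(len(level_clouds)))

    fig, ax = plt.subplots(figsize=(8, 4.5))
    for i, cloud in enumerate(level_clouds):
        sample = forward_generate(cloud, n_drops, seed=seed + i + 1)
        colour = LEVEL_COLOURS[i % len(LEVEL_COLOURS)]
        ax.scatter(sample.x, sample.mu, s=2, color=colour, label=labels[i])
    sample = forward_generate(assessed, n_drops, seed=seed)
    ax.scatter(sample.x, sample.mu, s=2, color="tab:blue", label=indicator)

    ax.set_xlim(left=0)  # concentrations are non-negative
    ax.set_ylim(0, 1.05)
    ax.set_xlabel(f"{indicator} value")
    ax.set_ylabel("membership degree")
    ax.set_title(title or f"{indicator} cloud vs standard clouds")
    ax.legend(markerscale=4, fontsize=8, loc="upper right")
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
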