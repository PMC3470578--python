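"""Mosaic-image rendering of NodeMaps.

The canonical outputs of the pipeline are TSV matrices; images are derived
artifacts. The default color scale runs blue over green to red; the inverted
flag reverses it (small values warm), and masked nodes render white.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LinearSegmentedColormap

from .errors import ValidationError
from .som_maps import IslandLabeling, NodeMap

__all__ = ["RenderSpec", "blue_green_red", "transform_values", "value_to_color", "render_heatmap"]


def blue_green_red(inverted: bool = False) -> LinearSegmentedColormap:
    colors = ["#0000ff", "#00cc00", "#ff0000"]
    if inverted:
        colors = colors[::-1]
    cmap = LinearSegmentedColormap.from_list("bgr", colors)
    cmap.set_bad("#ffffff")
    return cmap


@dataclass
class RenderSpec:
    """Rendering parameters for one mosaic image."""

    scale: str = "linear"  # 'linear' | 'log'
    inverted: bool = False
    vmin: float | None = None
    vmax: float | None = None
    mask_color: str = "#ffffff"
    border_color: str = "#000000"

    def __post_init__(self):
        if self.scale not in ("linear", "log"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.vmin is not None and self.vmax is not None and self.vmin >= self.vmax:
            raise ValidationError("vmin must be < vmax")

    @classmethod
    def for_map(cls, node_map: NodeMap) -> "RenderSpec":
        return cls(scale=node_map.scale, inverted=node_map.inverted)


def transform_values(values: np.ndarray, scale: str) -> np.ndarray:
    """Apply the scale transform: log10(v + 1) when zeros are present, log10
    for strictly positive maps, identity for linear."""
    values = np.asarray(values, dtype=float)
    if scale == "linear":
        return values
    finite = values[np.isfinite(values)]
    if finite.size and np.nanmin(finite) < 0:
        raise ValidationError("log scale requested for a map with negative values")
    if finite.size == 0 or np.nanmin(finite) == 0:
        return np.log10(values + 1.0)
    return np.log10(values)


def value_to_color(value: float, vmin: float, vmax: float, spec: RenderSpec):
    """Pure value -> RGBA mapping used by the mosaic (monotone in value)."""
    cmap = blue_green_red(spec.inverted)
    if not np.isfinite(value):
        return cmap.get_bad()
    if vmax == vmin:
        frac = 0.5
    else:
        frac = (value - vmin) / (vmax - vmin)
    return cmap(float(np.clip(frac, 0.0, 1.0)))


def render_heatmap(
    node_map: NodeMap,
    spec: RenderSpec | None = None,
    path=None,
    islands: IslandLabeling | None = None,
):
    """Render one tile per node at its grid position; masked nodes are white.

    Returns the matplotlib figure; saves to ``path`` when given. An optional
    island labeling overlays borders (sparse nodes) in the border color and
    prints island labels at their centroids.
    """
    spec = spec or RenderSpec.for_map(node_map)
    grid = transform_values(node_map.grid(), spec.scale)
    cmap = blue_green_red(spec.inverted)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(
        np.ma.masked_invalid(grid),
        cmap=cmap,
        vmin=spec.vmin,
        vmax=spec.vmax,
        interpolation="nearest",
        origin="upper",
    )
    if islands is not None:
        border = (islands.node_island < 0).reshape(islands.shape)
        overlay = np.ma.masked_where(~border, border.astype(float))
        ax.imshow(
            overlay,
            cmap=LinearSegmentedColormap.from_list("border", [spec.border_color] * 2),
            interpolation="nearest",
            origin="upper",
            alpha=0.6,
        )
        for isl, label in islands.labels.items():
            nodes = np.flatnonzero(islands.node_island == isl)
            rows, cols = np.divmod(nodes, islands.shape[1])
            ax.text(
                cols.mean(),
                rows.mean(),
                label,
                ha="center",
                va="center",
                fontsize=7,
                color="black",
            )
    ax.set_title(node_map.label)
    ax.set_xticks([])
    ax.set_yticks([])
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
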