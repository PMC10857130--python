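"""Heatmap grids, diagnostic spectra, QC statistics and multi-gas overlays.

A concentration column w (one W column from the unmixing) is reshaped in scan
order to the grid and min-max normalized to [0, 1]; the grid renders with row
0 at the top, matching the top-left scan origin.  Overlays blend per-gas maps
additively in RGB so co-located plumes mix colors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from matplotlib.colors import to_rgb

from .scan import ConcentrationMap, DimensionalError, GridGeometry, HyperspectralScan

__all__ = [
    "OverlayImage",
    "reshape_map",
    "flatten_map",
    "extract_diagonal",
    "spot_rsd",
    "overlay_maps",
    "save_map_csv",
    "render_map_png",
]


@dataclass
class OverlayImage:
    """Additive RGB composition of several concentration maps."""

    geometry: GridGeometry
    layers: tuple[tuple[ConcentrationMap, str], ...]
    rendered: np.ndarray  # (n_rows, n_cols, 3) floats in [0, 1]


def _normalize(grid: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant grids map to all zeros."""
    lo, hi = grid.min(), grid.max()
    if hi == lo:
        return np.zeros_like(grid)
    return (grid - lo) / (hi - lo)


def reshape_map(w: np.ndarray, geometry: GridGeometry) -> ConcentrationMap:
    """Reshape a length-n concentration column to the grid and normalize.

    The column is laid out in scan order (row-major from the top-left corner)
    and min-max normalized to [0, 1]; a constant column yields an all-zero map.
    """
    w = np.asarray(w, dtype=float).ravel()
    if w.size != geometry.n_points:
        raise DimensionalError(
            f"column length {w.size} does not match grid ({geometry.n_points})"
        )
    grid = w.reshape(geometry.n_rows, geometry.n_cols)
    return ConcentrationMap(geometry, _normalize(grid))


def flatten_map(cmap: ConcentrationMap) -> np.ndarray:
    """Scan-order flattening; inverse of the reshape step of :func:`reshape_map`."""
    return cmap.values.ravel().copy()


def extract_diagonal(scan: HyperspectralScan) -> np.ndarray:
    """Spectra at grid positions (i, i), top-left to bottom-right.

    Requires a square grid; returns an (n_rows, m) array.
    """
    g = scan.geometry
    if g.n_rows != g.n_cols:
        raise ValueError("diagonal extraction needs a square grid")
    idx = np.arange(g.n_rows) * g.n_cols + np.arange(g.n_rows)
    return scan.V[idx]


def spot_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100·sd/mean (sample sd, ddof=1).

    The spot-to-spot RSD of a characteristic peak's intensity is the standard
    uniformity statistic for SERS substrates.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = x.mean()
    if mean == 0:
        raise ZeroDivisionError("RSD undefined for zero-mean values")
    return float(100.0 * x.std(ddof=1) / mean)


def overlay_maps(
    maps: Sequence[ConcentrationMap],
    colors: Sequence[str],
) -> OverlayImage:
    """Blend concentration maps additively, one named color per map.

    Each pixel's RGB is Σ value_i · rgb(color_i), clipped to [0, 1], so
    disjoint plumes keep their own colors and overlapping plumes mix.
    """
    if len(maps) != len(colors):
        raise ValueError("one color per map required")
    if not maps:
        raise ValueError("at least one map required")
    geometry = maps[0].geometry
    for m in maps[1:]:
        if m.geometry != geometry:
            raise DimensionalError("all maps must share one geometry")
    rgb = np.zeros((geometry.n_rows, geometry.n_cols, 3))
    for m, color in zip(maps, colors):
        rgb += m.values[..., None] * np.asarray(to_rgb(color))
    rgb = np.clip(rgb, 0.0, 1.0)
    return OverlayImage(geometry, tuple(zip(maps, colors)), rgb)


def save_map_csv(cmap: ConcentrationMap, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, cmap.values, delimiter=",", fmt="%.17g")
    return path


def load_map_csv(path: str | Path, geometry: GridGeometry) -> ConcentrationMap:
    grid = np.loadtxt(path, delimiter=",")
    return ConcentrationMap(geometry, grid)


def render_map_png(
    cmap: ConcentrationMap | OverlayImage,
    path: str | Path,
    cmap_name: str = "viridis",
) -> Path:
    """Render a heatmap (or overlay) to PNG; row 0 at the top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    fig, ax = plt.subplots(figsize=(4, 4))
    g = cmap.geometry
    extent = (0.0, g.array_size, g.array_size, 0.0)  # y downward
    if isinstance(cmap, OverlayImage):
        ax.imshow(cmap.rendered, extent=extent, origin="upper")
    else:
        ax.imshow(cmap.values, cmap=cmap_name, extent=extent, origin="upper")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
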