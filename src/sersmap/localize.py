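"""Odor-source localization by elliptical 2D Gaussian fitting.

A concentration heatmap of a plume is modeled as a sum of up to three
axis-aligned elliptical Gaussians over a constant offset,

    F(x, y) = offset + Σᵢ Aᵢ · exp(−((x − x0ᵢ)²/(2σxᵢ²) + (y − y0ᵢ)²/(2σyᵢ²))),

in millimetre coordinates (pixel centers).  The fitted source size is
(σx + σy)/2, which is calibrated against the actual source diameter by
ordinary least squares.

Fits are seeded from local maxima of a lightly smoothed copy of the map (the
fit itself runs on the unsmoothed map) with moment-based σ starts, and solved
by bounded nonlinear least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize, stats

from .mapping import _normalize
from .scan import ConcentrationMap, GridGeometry, pixel_center_mm

__all__ = [
    "PlumeFit",
    "SizeCalibration",
    "FitFailure",
    "smooth_map",
    "find_peaks",
    "fit_gaussians",
    "fitted_diameter",
    "calibrate_size",
]

MAX_SOURCES = 3


class FitFailure(RuntimeError):
    """Gaussian fit did not converge; carries the best attempt."""

    def __init__(self, message: str, best: "list[PlumeFit] | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class PlumeFit:
    """One fitted plume: center (mm), widths (mm), amplitude and shared offset."""

    amplitude: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    offset: float
    residual_norm: float

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("fitted sigmas must be positive")


@dataclass(frozen=True)
class SizeCalibration:
    """OLS line fitted_diameter = slope·actual_diameter + intercept."""

    pairs: tuple[tuple[float, float], ...]
    slope: float
    intercept: float
    r_squared: float


def smooth_map(cmap: ConcentrationMap, sigma_px: float) -> ConcentrationMap:
    """Gaussian blur (reflective boundary) re-normalized to [0, 1].

    ``sigma_px`` is in pixels; 0 is the identity.  Reflective boundaries keep
    the pre-normalization total intensity conserved.
    """
    if sigma_px < 0:
        raise ValueError("smoothing sigma must be non-negative")
    if sigma_px == 0:
        return ConcentrationMap(cmap.geometry, cmap.values.copy())
    blurred = ndimage.gaussian_filter(cmap.values, sigma_px, mode="reflect")
    return ConcentrationMap(cmap.geometry, _normalize(blurred))


def _line_min(v: np.ndarray, a: tuple[int, int], b: tuple[int, int]) -> float:
    """Minimum map value along the pixel line from a to b."""
    n = int(max(abs(b[0] - a[0]), abs(b[1] - a[1]))) + 1
    rr = np.linspace(a[0], b[0], n).round().astype(int)
    cc = np.linspace(a[1], b[1], n).round().astype(int)
    return float(v[rr, cc].min())


def find_peaks(
    cmap: ConcentrationMap,
    k: int,
    min_separation_px: int = 6,
    min_height: float = 0.25,
    min_prominence: float = 0.1,
) -> list[tuple[int, int]]:
    """Up to k plume peaks as (row, col) seeds, tallest first.

    A pixel is a candidate when no 8-neighbor exceeds it, it rises above the
    map minimum (so constant maps yield none; symmetric plateau maxima are
    kept and deduplicated by suppression) and it reaches ``min_height`` times
    the map maximum.  Candidates closer than ``min_separation_px`` to an
    accepted taller seed are suppressed, and a candidate is only accepted when
    it rises at least ``min_prominence`` (relative to the map maximum) above
    its highest saddle toward any taller accepted peak — this rejects noise
    wiggles riding on the flank of a larger plume, which are tall but have
    almost no prominence, while a genuine second source is separated from the
    first by a deep valley.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    v = cmap.values
    if v.size == 0:
        raise ValueError("empty map")
    # 8-neighborhood maxima via a padded comparison; ties allowed so that a
    # peak centered between pixels (a 2×2 plateau) still seeds
    padded = np.pad(v, 1, mode="constant", constant_values=-np.inf)
    is_max = (v > v.min()) & (v >= min_height * v.max())
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == dc == 0:
                continue
            shifted = padded[1 + dr : 1 + dr + v.shape[0],
                             1 + dc : 1 + dc + v.shape[1]]
            is_max &= v >= shifted
    rows, cols = np.nonzero(is_max)
    if rows.size == 0:
        warnings.warn("no strict local maxima found", stacklevel=2)
        return []
    order = np.argsort(-v[rows, cols], kind="stable")
    seeds: list[tuple[int, int]] = []
    for i in order:
        r, c = int(rows[i]), int(cols[i])
        if any(np.hypot(r - r0, c - c0) < min_separation_px for r0, c0 in seeds):
            continue
        if seeds:
            saddle = max(_line_min(v, (r, c), s) for s in seeds)
            if v[r, c] - saddle < min_prominence * v.max():
                continue
        seeds.append((r, c))
        if len(seeds) == k:
            break
    return seeds


def _moment_sigma(v: np.ndarray, seed: tuple[int, int], pitch: float) -> tuple[float, float]:
    """Intensity-weighted spatial std around a seed, in mm, within a local window."""
    r0, c0 = seed
    half = max(3, int(round(3.0 / pitch)))  # ~3 mm window half-width
    rs = slice(max(0, r0 - half), min(v.shape[0], r0 + half + 1))
    cs = slice(max(0, c0 - half), min(v.shape[1], c0 + half + 1))
    w = v[rs, cs] - v[rs, cs].min()
    if w.sum() <= 0:
        return pitch * 2, pitch * 2
    rr, cc = np.mgrid[rs, cs]
    mr = (w * rr).sum() / w.sum()
    mc = (w * cc).sum() / w.sum()
    sr = np.sqrt((w * (rr - mr) ** 2).sum() / w.sum())
    sc = np.sqrt((w * (cc - mc) ** 2).sum() / w.sum())
    return max(sc * pitch, pitch / 2), max(sr * pitch, pitch / 2)


def _model(params: np.ndarray, k: int, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    out = np.full_like(X, params[-1])  # shared offset is the last parameter
    for i in range(k):
        A, x0, y0, sx, sy = params[5 * i : 5 * i + 5]
        out += A * np.exp(-((X - x0) ** 2 / (2 * sx**2) + (Y - y0) ** 2 / (2 * sy**2)))
    return out


def fit_gaussians(
    cmap: ConcentrationMap,
    k: int = 1,
    seeds: Sequence[tuple[int, int]] | None = None,
    smooth_sigma_px: float = 1.0,
    max_restarts: int = 3,
) -> list[PlumeFit]:
    """Fit k elliptical Gaussians plus a shared constant offset to a map.

    Initial centers come from ``seeds`` (grid (row, col)) or from
    :func:`find_peaks` applied to a copy smoothed by ``smooth_sigma_px``; σ
    starts are moment-based.  The fit runs on the unsmoothed map with σ
    bounded to [pitch/2, array_size].  Returns one PlumeFit per source,
    ordered by descending amplitude.

    Raises :class:`FitFailure` (carrying the best attempt) if no restart
    converges; if fewer than k peaks are found, the fit proceeds with the
    reduced count under a warning.
    """
    if not 1 <= k <= MAX_SOURCES:
        raise ValueError(f"k must be in [1, {MAX_SOURCES}]")
    g = cmap.geometry
    v = cmap.values
    if v.max() == v.min():
        raise ValueError("cannot fit a constant map")

    if seeds is None:
        seeds = find_peaks(smooth_map(cmap, smooth_sigma_px), k)
        if len(seeds) < k:
            warnings.warn(
                f"only {len(seeds)} peak(s) found for k={k}; fitting fewer sources",
                stacklevel=2,
            )
            k = max(len(seeds), 1)
            if not seeds:
                seeds = [tuple(np.unravel_index(np.argmax(v), v.shape))]
    seeds = list(seeds)[:k]

    pitch = g.pitch
    x = (np.arange(g.n_cols) + 0.5) * pitch
    y = (np.arange(g.n_rows) + 0.5) * pitch
    X, Y = np.meshgrid(x, y)

    lo, hi = [], []
    p0 = []
    for r, c in seeds:
        sx0, sy0 = _moment_sigma(v, (r, c), pitch)
        cx, cy = pixel_center_mm(r, c, g)
        p0 += [v[r, c] - v.min(), cx, cy, sx0, sy0]
        lo += [0.0, -pitch, -pitch, pitch / 2, pitch / 2]
        hi += [2.0, g.array_size + pitch, g.array_size + pitch, g.array_size, g.array_size]
    p0.append(float(v.min()))
    lo.append(0.0)
    hi.append(1.0)

    def residuals(p: np.ndarray) -> np.ndarray:
        return (_model(p, k, X, Y) - v).ravel()

    rng = np.random.default_rng(0)
    best = None
    start = np.asarray(p0)
    for attempt in range(max_restarts + 1):
        trial = start if attempt == 0 else np.clip(
            start * rng.uniform(0.8, 1.2, start.size), lo, hi
        )
        sol = optimize.least_squares(residuals, trial, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            best = sol if sol.cost <= best.cost else best
            break

    fits = []
    res_norm = float(np.sqrt(2 * best.cost))
    offset = float(best.x[-1])
    for i in range(k):
        A, x0, y0, sx, sy = best.x[5 * i : 5 * i + 5]
        fits.append(PlumeFit(float(A), float(x0), float(y0), float(sx), float(sy),
                             offset, res_norm))
    fits.sort(key=lambda f: -f.amplitude)
    if not best.success:
        raise FitFailure("Gaussian fit did not converge", best=fits)
    return fits


def fitted_diameter(fit: PlumeFit) -> float:
    """Source-size estimate in mm: (σx + σy) / 2."""
    return (fit.sigma_x + fit.sigma_y) / 2.0


def calibrate_size(pairs: Sequence[tuple[float, float]]) -> SizeCalibration:
    """OLS regression of fitted diameter on actual diameter, with R².

    ``pairs`` are (actual_mm, fitted_mm); requires ≥ 2 pairs with
    non-constant actual diameters.
    """
    pairs = tuple((float(a), float(f)) for a, f in pairs)
    if len(pairs) < 2:
        raise ValueError("calibration needs at least two pairs")
    actual = np.array([p[0] for p in pairs])
    fitted = np.array([p[1] for p in pairs])
    if np.all(actual == actual[0]):
        raise ValueError("degenerate regression: all actual diameters equal")
    res = stats.linregress(actual, fitted)
    return SizeCalibration(
        pairs=pairs,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )
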