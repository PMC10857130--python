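"""Core data types, coordinate conventions, and tabular I/O for array scans.

A hyperspectral scan is a grid of measurement points (default 36 × 36 over a
15 mm × 15 mm sensor array) each carrying a full Raman spectrum (default 308
channels at ~4 cm⁻¹ spacing).  Spectra are stored row-major in scan order,
i.e. from the top-left corner of the array to the bottom-right corner, so the
flat spectrum index k maps to grid position (k // n_cols, k % n_cols).

Physical coordinates are pixel centers in millimetres: x increases rightward,
y increases downward, origin at the array's top-left corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberAxis",
    "GridGeometry",
    "HyperspectralScan",
    "ConcentrationMap",
    "LabeledSpectrumDataset",
    "DimensionalError",
    "flat_index",
    "grid_position",
    "pixel_center_mm",
    "read_scan",
    "write_scan",
    "read_dataset",
    "write_dataset",
]

#: Canonical number of Raman-shift channels per spectrum.
N_CHANNELS = 308

#: Canonical grid: 36 × 36 points over a 15 mm × 15 mm array.
N_POINTS_PER_SIDE = 36
ARRAY_SIZE_MM = 15.0

#: Class labels for feature spectra.
LABEL_INTERFERENCE, LABEL_BZD, LABEL_EBZD = 0, 1, 2
VALID_LABELS = frozenset({LABEL_INTERFERENCE, LABEL_BZD, LABEL_EBZD})


class DimensionalError(ValueError):
    """Shape of data does not match the declared geometry or axis."""


@dataclass(frozen=True)
class WavenumberAxis:
    """Ordered Raman-shift axis in cm⁻¹.

    Parameters
    ----------
    values
        Strictly increasing, finite Raman shifts (cm⁻¹), length ≥ 2.
    resolution_hint
        Nominal channel spacing (cm⁻¹); informational only.
    """

    values: np.ndarray
    resolution_hint: float = 4.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis needs at least 2 wavenumbers")
        if not np.all(np.isfinite(v)):
            raise ValueError("axis values must be finite")
        if not np.all(np.diff(v) > 0):
            raise ValueError("axis values must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def index_of(self, wavenumber: float) -> int:
        """Index of the channel closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))


@dataclass(frozen=True)
class GridGeometry:
    """Scan-grid layout: point counts and physical size of the square array."""

    n_rows: int = N_POINTS_PER_SIDE
    n_cols: int = N_POINTS_PER_SIDE
    array_size: float = ARRAY_SIZE_MM  # physical edge length, mm

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.array_size <= 0:
            raise ValueError("array_size must be positive")

    @property
    def pitch(self) -> float:
        """Center-to-center point spacing in mm."""
        return self.array_size / self.n_cols

    @property
    def n_points(self) -> int:
        return self.n_rows * self.n_cols


def flat_index(row: int, col: int, geometry: GridGeometry) -> int:
    """Flat scan-order index of grid point (row, col); row-major, top-left origin."""
    if not (0 <= row < geometry.n_rows and 0 <= col < geometry.n_cols):
        raise IndexError(f"grid position ({row}, {col}) out of range")
    return row * geometry.n_cols + col


def grid_position(k: int, geometry: GridGeometry) -> tuple[int, int]:
    """Inverse of :func:`flat_index`: (row, col) of flat index k."""
    if not 0 <= k < geometry.n_points:
        raise IndexError(f"flat index {k} out of range")
    return divmod(k, geometry.n_cols)


def pixel_center_mm(row: int, col: int, geometry: GridGeometry) -> tuple[float, float]:
    """Physical (x, y) center of a grid point in mm.

    x runs rightward, y downward, both from the array's top-left corner, so the
    point (0, 0) sits half a pitch in from the corner.
    """
    if not (0 <= row < geometry.n_rows and 0 <= col < geometry.n_cols):
        raise IndexError(f"grid position ({row}, {col}) out of range")
    p = geometry.pitch
    return (col + 0.5) * p, (row + 0.5) * p


@dataclass
class HyperspectralScan:
    """A full array scan: (n_rows·n_cols) × m intensity matrix plus metadata."""

    geometry: GridGeometry
    axis: WavenumberAxis
    V: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if V.ndim != 2:
            raise DimensionalError("scan matrix must be 2-D")
        if V.shape[0] != self.geometry.n_points:
            raise DimensionalError(
                f"scan has {V.shape[0]} spectra, geometry expects "
                f"{self.geometry.n_points}"
            )
        if V.shape[1] != len(self.axis):
            raise DimensionalError(
                f"scan has {V.shape[1]} channels, axis has {len(self.axis)}"
            )
        if not np.all(np.isfinite(V)):
            raise ValueError("scan intensities must be finite")
        self.V = V

    @property
    def n(self) -> int:
        return self.V.shape[0]

    @property
    def m(self) -> int:
        return self.V.shape[1]

    def spectrum_at(self, row: int, col: int) -> np.ndarray:
        return self.V[flat_index(row, col, self.geometry)]


@dataclass
class ConcentrationMap:
    """One NMF component's spatial weights as an n_rows × n_cols grid in [0, 1]."""

    geometry: GridGeometry
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.geometry.n_rows, self.geometry.n_cols):
            raise DimensionalError(
                f"map shape {v.shape} does not match geometry "
                f"({self.geometry.n_rows}, {self.geometry.n_cols})"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("map values must be finite")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("map values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass
class LabeledSpectrumDataset:
    """Feature spectra with class labels 0 = interference, 1 = BZD, 2 = EBZD."""

    spectra: np.ndarray  # (n_samples, L)
    labels: np.ndarray  # (n_samples,) ints in {0, 1, 2}
    split_tag: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.spectra, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        if X.ndim != 2:
            raise DimensionalError("spectra must form a 2-D array")
        if y.shape != (X.shape[0],):
            raise DimensionalError("one label per spectrum required")
        if not set(np.unique(y)) <= VALID_LABELS:
            raise ValueError(f"labels must be in {sorted(VALID_LABELS)}")
        if not np.all(np.isfinite(X)):
            raise ValueError("spectra must be finite")
        self.spectra = X
        self.labels = y

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def length(self) -> int:
        return self.spectra.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {int(c): int((self.labels == c).sum()) for c in sorted(VALID_LABELS)}

    def subset(self, idx: Iterable[int], split_tag: str | None = None) -> "LabeledSpectrumDataset":
        idx = np.asarray(list(idx), dtype=int)
        return LabeledSpectrumDataset(
            self.spectra[idx], self.labels[idx],
            self.split_tag if split_tag is None else split_tag,
        )


# ---------------------------------------------------------------------------
# Tabular I/O.  Matrix bodies are headerless CSV so round-trips are bit-exact
# and language-neutral; geometry/axis/metadata travel in a JSON sidecar.
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def read_scan(
    path: str | Path,
    geometry: GridGeometry,
    axis: WavenumberAxis,
    metadata: dict[str, Any] | None = None,
) -> HyperspectralScan:
    """Read a headerless CSV (one row per grid point in scan order) as a scan.

    Raises
    ------
    DimensionalError
        If the file's shape disagrees with ``geometry``/``axis``.
    ValueError
        If a cell is not numeric.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, dtype=float)
    except ValueError as exc:  # non-numeric cell
        raise ValueError(f"non-numeric data in {path}: {exc}") from exc
    V = df.to_numpy()
    if V.shape != (geometry.n_points, len(axis)):
        raise DimensionalError(
            f"{path} has shape {V.shape}, expected "
            f"({geometry.n_points}, {len(axis)})"
        )
    return HyperspectralScan(geometry, axis, V, metadata or {})


def write_scan(scan: HyperspectralScan, path: str | Path) -> Path:
    """Write the scan matrix as headerless CSV plus a JSON sidecar.

    The sidecar carries geometry, axis and metadata so ``load_scan`` can
    rebuild the object; :func:`read_scan` with explicit geometry/axis ignores it.
    """
    path = Path(path)
    # repr-precision floats round-trip exactly through text
    np.savetxt(path, scan.V, delimiter=",", fmt="%.17g")
    side = {
        "n_rows": scan.geometry.n_rows,
        "n_cols": scan.geometry.n_cols,
        "array_size_mm": scan.geometry.array_size,
        "wavenumbers": scan.axis.values.tolist(),
        "resolution_hint": scan.axis.resolution_hint,
    }
    if scan.metadata:
        side["metadata"] = scan.metadata
    _sidecar_path(path).write_text(json.dumps(side, indent=1))
    return path


def load_scan(path: str | Path) -> HyperspectralScan:
    """Read a scan written by :func:`write_scan`, using its JSON sidecar."""
    path = Path(path)
    side = json.loads(_sidecar_path(path).read_text())
    geometry = GridGeometry(side["n_rows"], side["n_cols"], side["array_size_mm"])
    axis = WavenumberAxis(np.asarray(side["wavenumbers"]), side.get("resolution_hint", 4.0))
    return read_scan(path, geometry, axis, side.get("metadata"))


def write_dataset(dataset: LabeledSpectrumDataset, path: str | Path) -> Path:
    """Write a labeled dataset as CSV: feature columns then a final label column."""
    path = Path(path)
    df = pd.DataFrame(dataset.spectra)
    df["label"] = dataset.labels
    df.to_csv(path, index=False, header=False, float_format="%.17g")
    return path


def read_dataset(
    path: str | Path,
    expected_length: int = N_CHANNELS,
    split_tag: str = "",
) -> LabeledSpectrumDataset:
    """Read a labeled dataset CSV (last column = integer label).

    Spectra shorter than ``expected_length`` (e.g. 307-channel exports) are
    right-padded with their last value so every consumer sees a fixed length.
    """
    df = pd.read_csv(path, header=None)
    y = df.iloc[:, -1].to_numpy(dtype=int)
    X = df.iloc[:, :-1].to_numpy(dtype=float)
    if X.shape[1] < expected_length:
        pad = np.repeat(X[:, -1:], expected_length - X.shape[1], axis=1)
        X = np.hstack([X, pad])
    elif X.shape[1] > expected_length:
        raise DimensionalError(
            f"dataset has {X.shape[1]} features, expected ≤ {expected_length}"
        )
    return LabeledSpectrumDataset(X, y, split_tag)
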